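"""Fossil-record diversification statistics over geological time bins.

Works from a per-stage species table (stage name, boundary ages, new
species appearances and standing richness for eutherians and for mammals
as a whole).  Stages are combined into time bins by a minimum-sampling
rule — a few critical, well-sampled stages are kept as their own bins and
the rest are merged oldest-first until each bin samples a minimum number
of mammal species — and two statistics are computed per bin:

* diversification rate: new eutherian appearances divided by bin duration
  and by eutherian standing richness in the previous bin (a per-capita
  origination rate, with the previous bin's richness as the starting-stock
  proxy);
* eutherian proportion: new eutherian appearances as a fraction of new
  mammal appearances, optionally averaged over named groups of bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeBin",
    "BinningConfig",
    "build_bins",
    "diversification_rate",
    "eutherian_proportion",
    "read_stage_table",
    "bins_to_frame",
    "toy_stage_table",
]

STAGE_COLUMNS = [
    "stage",
    "start_Ma",
    "end_Ma",
    "eutherian_new",
    "eutherian_richness",
    "mammal_new",
    "mammal_richness",
]


@dataclass(frozen=True)
class TimeBin:
    """One time bin: boundary ages in Ma (start older than end) and fossil
    counts.  ``flagged`` marks bins kept despite failing the sampling rule."""

    name: str
    start_ma: float
    end_ma: float
    eutherian_new: int
    eutherian_richness: int
    mammal_new: int
    mammal_richness: int
    stages: tuple[str, ...] = ()
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.start_ma > self.end_ma:
            raise ValueError(f"bin {self.name!r}: start age must exceed end age")
        counts = (self.eutherian_new, self.eutherian_richness, self.mammal_new, self.mammal_richness)
        if any(c < 0 for c in counts):
            raise ValueError(f"bin {self.name!r}: counts must be non-negative")
        if self.eutherian_new > self.eutherian_richness or self.mammal_new > self.mammal_richness:
            raise ValueError(f"bin {self.name!r}: new appearances cannot exceed standing richness")
        if not self.stages:
            object.__setattr__(self, "stages", (self.name,))

    @property
    def duration_ma(self) -> float:
        return self.start_ma - self.end_ma


@dataclass(frozen=True)
class BinningConfig:
    """Stage-merging rule: keep ``fixed_bins`` as-is and merge the remaining
    stages (oldest first, within each run between fixed bins) until every
    bin samples at least ``min_mammal_species`` mammal species."""

    min_mammal_species: int = 80
    fixed_bins: tuple[str, ...] = ("Campanian", "Maastrichtian", "Paleocene")
    previous_bin_override: dict[str, str] = field(
        default_factory=lambda: {"Albian-Cenomanian": "Barremian-Aptian"}
    )

    def __post_init__(self) -> None:
        if self.min_mammal_species < 1:
            raise ValueError("minimum species per bin must be >= 1")


def toy_stage_table() -> pd.DataFrame:
    """Packaged synthetic stage table (hand-picked counts for worked
    examples and tests; not real fossil data)."""
    from importlib import resources

    with resources.files("errorshift.data").joinpath("toy_stage_table_synthetic.csv").open() as fh:
        return pd.read_csv(fh)


def read_stage_table(path: str | Path) -> pd.DataFrame:
    """Read a per-stage species CSV with the columns
    stage,start_Ma,end_Ma,eutherian_new,eutherian_richness,mammal_new,mammal_richness."""
    df = pd.read_csv(path)
    missing = set(STAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stage table lacks columns: {sorted(missing)}")
    return df[STAGE_COLUMNS]


def _merge(run: list[pd.Series], flagged: bool = False) -> TimeBin:
    name = run[0]["stage"] if len(run) == 1 else f"{run[0]['stage']}-{run[-1]['stage']}"
    return TimeBin(
        name=name,
        start_ma=float(run[0]["start_Ma"]),
        end_ma=float(run[-1]["end_Ma"]),
        eutherian_new=int(sum(r["eutherian_new"] for r in run)),
        eutherian_richness=int(sum(r["eutherian_richness"] for r in run)),
        mammal_new=int(sum(r["mammal_new"] for r in run)),
        mammal_richness=int(sum(r["mammal_richness"] for r in run)),
        stages=tuple(r["stage"] for r in run),
        flagged=flagged,
    )


def build_bins(stage_table: pd.DataFrame, config: BinningConfig | None = None) -> list[TimeBin]:
    """Combine ordered stages into time bins under the minimum-sampling rule.

    The table must be ordered oldest first (descending ``start_Ma``);
    adjacent stage boundaries must match (no gaps or overlaps).  Fixed bins
    are emitted unchanged; other stages are accumulated oldest-first and
    flushed once the merged mammal species count reaches the minimum.  A
    trailing accumulation that cannot reach the minimum (at the record's end
    or where it abuts a fixed bin) is kept but flagged, with a warning.
    """
    config = config or BinningConfig()
    df = stage_table.reset_index(drop=True)
    if not df["start_Ma"].is_monotonic_decreasing:
        raise ValueError("stages must be ordered oldest first")
    for i in range(1, len(df)):
        if not np.isclose(df.loc[i - 1, "end_Ma"], df.loc[i, "start_Ma"]):
            raise ValueError(
                f"stage boundaries must be contiguous: {df.loc[i-1,'stage']} ends "
                f"{df.loc[i-1,'end_Ma']} but {df.loc[i,'stage']} starts {df.loc[i,'start_Ma']}"
            )

    bins: list[TimeBin] = []
    run: list[pd.Series] = []

    def flush(force: bool) -> None:
        nonlocal run
        if not run:
            return
        total = sum(r["mammal_richness"] for r in run)
        ok = total >= config.min_mammal_species
        if ok or force:
            if not ok:
                warnings.warn(
                    f"bin {run[0]['stage']}..{run[-1]['stage']} samples only {total} mammal "
                    f"species (< {config.min_mammal_species}); kept but flagged",
                    stacklevel=3,
                )
            bins.append(_merge(run, flagged=not ok))
            run = []

    for _, row in df.iterrows():
        if row["stage"] in config.fixed_bins:
            flush(force=True)
            bins.append(_merge([row]))
        else:
            run.append(row)
            flush(force=False)
    flush(force=True)
    return bins


def diversification_rate(
    bins: list[TimeBin],
    previous_override: dict[str, str] | None = None,
    allow_missing_previous: bool = False,
) -> pd.DataFrame:
    """Per-capita eutherian appearance rate per bin.

    rate = new eutherian appearances / (bin duration in Ma x eutherian
    standing richness of the previous, i.e. next-older, bin).  A named
    override can redirect the previous bin (the oldest plotted bin typically
    borrows an older reference bin).  Bins with no resolvable previous bin
    raise unless ``allow_missing_previous``; a previous richness of zero
    yields a flagged NaN rate.
    """
    previous_override = {**(previous_override or {})}
    by_name = {b.name: i for i, b in enumerate(bins)}
    rows = []
    for i, b in enumerate(bins):
        if b.name in previous_override:
            prev_name = previous_override[b.name]
            if prev_name not in by_name:
                raise KeyError(f"previous-bin override for {b.name!r} names unknown bin {prev_name!r}")
            prev = bins[by_name[prev_name]]
        elif i > 0:
            prev = bins[i - 1]
        elif allow_missing_previous:
            prev = None
        else:
            raise ValueError(f"bin {b.name!r} has no previous bin and no override")
        if prev is None or prev.eutherian_richness == 0:
            rate = np.nan
            flagged = True
        else:
            rate = b.eutherian_new / (b.duration_ma * prev.eutherian_richness)
            flagged = b.flagged
        rows.append(
            {
                "bin": b.name,
                "start_Ma": b.start_ma,
                "end_Ma": b.end_ma,
                "duration_Ma": b.duration_ma,
                "eutherian_new": b.eutherian_new,
                "previous_bin": prev.name if prev is not None else None,
                "previous_richness": prev.eutherian_richness if prev is not None else np.nan,
                "rate": rate,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def eutherian_proportion(
    bins: list[TimeBin],
    grouping: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Eutherian share of new mammal appearances.

    Per bin: new eutherian / new mammal appearances (flagged NaN when no
    mammal appearances).  With ``grouping`` (group name -> bin names), each
    group additionally gets the unweighted mean of its per-bin proportions
    — the headline statistic — plus the pooled-count alternative for
    transparency.
    """
    per_bin = pd.DataFrame(
        {
            "eutherian_new": [b.eutherian_new for b in bins],
            "mammal_new": [b.mammal_new for b in bins],
        },
        index=pd.Index([b.name for b in bins], name="bin"),
    )
    per_bin["proportion"] = np.where(
        per_bin["mammal_new"] > 0, per_bin["eutherian_new"] / per_bin["mammal_new"], np.nan
    )
    per_bin["flagged"] = per_bin["mammal_new"] == 0
    if grouping is None:
        return per_bin
    rows = {}
    for group, names in grouping.items():
        missing = set(names) - set(per_bin.index)
        if missing:
            raise KeyError(f"group {group!r} names unknown bins: {sorted(missing)}")
        sub = per_bin.loc[list(names)]
        if sub["flagged"].any():
            raise ValueError(f"group {group!r} contains bins with no new mammal appearances")
        rows[group] = {
            "mean_proportion": float(sub["proportion"].mean()),
            "pooled_proportion": float(sub["eutherian_new"].sum() / sub["mammal_new"].sum()),
            "n_bins": len(sub),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("group")


def bins_to_frame(bins: list[TimeBin]) -> pd.DataFrame:
    """Tidy per-bin table (one row per bin, constituent stages listed)."""
    return pd.DataFrame(
        {
            "bin": [b.name for b in bins],
            "start_Ma": [b.start_ma for b in bins],
            "end_Ma": [b.end_ma for b in bins],
            "duration_Ma": [b.duration_ma for b in bins],
            "eutherian_new": [b.eutherian_new for b in bins],
            "eutherian_richness": [b.eutherian_richness for b in bins],
            "mammal_new": [b.mammal_new for b in bins],
            "mammal_richness": [b.mammal_richness for b in bins],
            "stages": ["+".join(b.stages) for b in bins],
            "flagged": [b.flagged for b in bins],
        }
    ).set_index("bin")
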