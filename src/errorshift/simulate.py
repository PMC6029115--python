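"""Simulate nucleotide alignments along a dated tree with per-branch rates.

The root sequence is drawn from the substitution model's equilibrium
frequencies and evolved independently per site down the tree; each branch's
expected substitutions/site is its rate (subs/site/Ma) times its duration
(Ma).  Alignments carry a site-pattern compression table used by the
likelihood engine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rates import RateScheme, draw_branch_rates, expected_substitutions
from .submodels import ALPHABET, SubstitutionModel, jc69
from .timetree import Timetree

__all__ = ["Alignment", "SimulationConfig", "simulate_alignment", "write_replicates"]

_CODE = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulation batch (defaults follow the study design:
    20,000-bp alignments, 100 replicates)."""

    length: int = 20_000
    n_replicates: int = 100
    model: SubstitutionModel = field(default_factory=jc69)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_replicates < 1:
            raise ValueError("length and replicate count must be >= 1")


class Alignment:
    """Nucleotide matrix (taxa x sites) with site-pattern compression.

    The matrix is stored as uint8 codes into ``ACGT``; ``patterns`` /
    ``pattern_counts`` give the distinct site columns and their multiplicities
    (counts always sum to the alignment length).
    """

    def __init__(self, names: list[str], matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or len(names) != matrix.shape[0]:
            raise ValueError("need one matrix row per taxon")
        if matrix.size and matrix.max() > 3:
            raise ValueError("alignment alphabet is restricted to A, C, G, T")
        self.names = list(names)
        self.matrix = matrix
        self._patterns: np.ndarray | None = None
        self._counts: np.ndarray | None = None

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def _compress(self) -> None:
        if self._patterns is None:
            if self.n_sites == 0:
                self._patterns = np.zeros((self.n_taxa, 0), dtype=np.uint8)
                self._counts = np.zeros(0, dtype=np.int64)
            else:
                cols, counts = np.unique(self.matrix.T, axis=0, return_counts=True)
                self._patterns = cols.T.copy()
                self._counts = counts
    @property
    def patterns(self) -> np.ndarray:
        self._compress()
        return self._patterns

    @property
    def pattern_counts(self) -> np.ndarray:
        self._compress()
        return self._counts

    # -- text IO -------------------------------------------------------------

    @classmethod
    def from_strings(cls, named_seqs: dict[str, str]) -> "Alignment":
        names = list(named_seqs)
        rows = []
        for name in names:
            seq = named_seqs[name].upper()
            try:
                rows.append([_CODE[b] for b in seq])
            except KeyError as e:
                raise ValueError(f"sequence {name!r} contains non-ACGT symbol {e.args[0]!r}") from None
        lens = {len(r) for r in rows}
        if len(lens) > 1:
            raise ValueError("all sequences must have equal length")
        return cls(names, np.array(rows, dtype=np.uint8))

    def to_strings(self) -> dict[str, str]:
        return {n: "".join(ALPHABET[c] for c in row) for n, row in zip(self.names, self.matrix)}

    def _biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            SeqRecord(Seq(s), id=n, description="") for n, s in self.to_strings().items()
        )

    def write_fasta(self, path: str | Path) -> None:
        SeqIO.write(self._biopython(), str(path), "fasta")

    def write_phylip(self, path: str | Path) -> None:
        AlignIO.write(self._biopython(), str(path), "phylip-relaxed")

    @classmethod
    def read(cls, path: str | Path, fmt: str | None = None) -> "Alignment":
        """Read FASTA or relaxed PHYLIP (inferred from the suffix if ``fmt``
        is None)."""
        if fmt is None:
            fmt = "phylip-relaxed" if Path(path).suffix in {".phy", ".phylip"} else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls.from_strings({rec.id: str(rec.seq) for rec in aln})


def simulate_alignment(
    tree: Timetree,
    rates: np.ndarray,
    model: SubstitutionModel | None = None,
    length: int = 20_000,
    seed: int | np.random.Generator | None = None,
) -> Alignment:
    """Evolve ``length`` iid sites down ``tree`` and return the tip alignment.

    ``rates`` gives subs/site/Ma per branch (indexed by child node); the
    expected substitutions on a branch are rate x duration.  Default model is
    JC69.
    """
    if length < 1:
        raise ValueError("alignment length must be positive")
    model = model or jc69()
    blen = expected_substitutions(tree, rates)  # validates coverage
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    states = np.empty((tree.n_nodes, length), dtype=np.uint8)
    root = tree.root
    states[root] = rng.choice(4, size=length, p=model.freqs)
    for v in tree.preorder:
        if v == root:
            continue
        cum = model.transition_matrix(blen[v]).cumsum(axis=1)
        u = rng.random(length)
        states[v] = (u[:, None] > cum[states[tree.parent[v]]]).sum(axis=1)
    tips = tree.tip_indices
    return Alignment([tree.labels[i] for i in tips], states[tips])


def write_replicates(
    tree: Timetree,
    scheme: RateScheme,
    config: SimulationConfig,
    out_dir: str | Path,
    fmt: str = "phylip",
) -> Path:
    """Simulate ``config.n_replicates`` alignments and write them to disk.

    Produces one alignment file per replicate, a per-replicate true-rate CSV
    (branch id, rate) and a ``manifest.csv`` (replicate, seed, scheme, path);
    returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = {"phylip": ".phy", "fasta": ".fasta"}[fmt]
    root_ss = np.random.SeedSequence(config.seed)
    manifest = out / "manifest.csv"
    branch_ids = [tree.labels[i] or f"node{i}" for i in tree.branch_ids]
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["replicate", "seed", "scheme", "path"])
        for rep, ss in enumerate(root_ss.spawn(config.n_replicates), start=1):
            rng = np.random.default_rng(ss)
            rates = draw_branch_rates(tree, scheme, rng)
            aln = simulate_alignment(tree, rates, config.model, config.length, rng)
            path = out / f"rep{rep:03d}{ext}"
            (aln.write_phylip if fmt == "phylip" else aln.write_fasta)(path)
            with open(out / f"rep{rep:03d}_rates.csv", "w", newline="") as rf:
                rw = csv.writer(rf)
                rw.writerow(["branch", "rate_subs_per_site_per_Ma"])
                for bid, node in zip(branch_ids, tree.branch_ids):
                    rw.writerow([bid, repr(float(rates[node]))])
            w.writerow([rep, ss.entropy, scheme.name, path.name])
    return manifest
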