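"""Cross-cohort progress statistics and target-feature computations.

Comparing prediction rounds with different target mixes requires
difficulty-matched samples: targets are matched one-to-one by baseline
first-model DockQ with the Hungarian algorithm, or resampled with weights
from the ratio of Gaussian-KDE difficulty densities.  MSA diversity is
summarised as Neff, the effective sequence count after redundancy
down-weighting at an identity threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import gaussian_kde

from .interfaces import extract_interfaces, find_contacts
from .structures import Assembly

__all__ = [
    "DifficultySet",
    "MSA",
    "read_msa",
    "hungarian_match",
    "kde_weighted_bootstrap",
    "interface_msa_slice",
    "neff",
    "complex_features",
]


@dataclass
class DifficultySet:
    """Per-target difficulty scores (baseline first-model DockQ, in [0, 1])."""

    targets: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.targets) != len(self.scores):
            raise ValueError("targets and scores must have equal length")
        if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("difficulty scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.targets)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DifficultySet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df.iloc[:, 0].astype(str).tolist(),
                   df.iloc[:, 1].to_numpy(dtype=float))


def hungarian_match(a: DifficultySet, b: DifficultySet
                    ) -> tuple[list[tuple[int, int]], float]:
    """Optimal one-to-one matching minimising summed |difficulty differences|.

    Unequal sizes are allowed; min(len(a), len(b)) pairs are returned as
    (index in a, index in b), sorted by index in a.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both difficulty sets must be non-empty")
    cost = np.abs(a.scores[:, None] - b.scores[None, :])
    rows, cols = linear_sum_assignment(cost)
    pairing = sorted(zip(rows.tolist(), cols.tolist()))
    total = float(cost[rows, cols].sum())
    return pairing, total


def kde_weighted_bootstrap(source: DifficultySet, reference: DifficultySet,
                           n_samples: int, sample_size: int, seed: int,
                           bw_method: str | float = "scott",
                           weight_clip: float = 20.0) -> np.ndarray:
    """Resample source targets so their difficulty distribution matches the
    reference.

    Gaussian KDEs are fitted to both difficulty sets; each source point is
    weighted by density_reference/density_source (clipped, normalised) and
    sampled with replacement.  Returns an (n_samples, sample_size) array of
    indices into the source set.
    """
    if len(source) < 2 or len(reference) < 2:
        raise ValueError("both sets need at least 2 points for a KDE")
    kde_src = gaussian_kde(source.scores, bw_method=bw_method)
    kde_ref = gaussian_kde(reference.scores, bw_method=bw_method)
    dens_src = kde_src(source.scores)
    dens_ref = kde_ref(source.scores)
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(dens_src > 0, dens_ref / dens_src, 0.0)
    weights = np.clip(weights, 0.0, weight_clip)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all resampling weights are zero")
    weights = weights / total
    rng = np.random.default_rng(seed)
    return rng.choice(len(source), size=(n_samples, sample_size), p=weights)


@dataclass
class MSA:
    """Aligned sequences over a gapped alphabet; the first row is the query.

    ``blocks`` optionally records the column spans of the concatenated
    chains in a paired alignment, e.g. [(0, 120), (120, 250)].
    """

    sequences: list[str]
    ids: list[str] = field(default_factory=list)
    blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            return
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("all MSA rows must have equal length")
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)


def read_msa(path: str | Path) -> MSA:
    """Read FASTA or A3M; lowercase (insert) columns are removed on read."""
    from Bio import SeqIO

    ids, seqs = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append("".join(c for c in str(record.seq) if not c.islower()))
    return MSA(seqs, ids)


def interface_msa_slice(msa: MSA, positions=None, mode: str = "homo",
                        blocks: list[tuple[int, int]] | None = None) -> MSA:
    """Slice an MSA down to the columns of one interface.

    ``homo``: keep the columns of the single protein; rows are never dropped.
    ``hetero``: keep the columns of both blocks and drop rows that are
    all-gap in either block (sequences must cover both partners).
    """
    blocks = blocks or msa.blocks
    if mode == "homo":
        cols = sorted(positions) if positions is not None else \
            list(range(*blocks[0])) if blocks else list(range(msa.n_columns))
        if cols and cols[-1] >= msa.n_columns:
            raise ValueError("positions out of column range")
        return MSA([("".join(s[c] for c in cols)) for s in msa.sequences],
                   list(msa.ids))
    if mode != "hetero":
        raise ValueError(f"unknown mode {mode!r}")
    if not blocks or len(blocks) < 2:
        raise ValueError("hetero mode requires two chain blocks")
    (a0, a1), (b0, b1) = blocks[0], blocks[1]
    seqs, ids = [], []
    for sid, seq in zip(msa.ids, msa.sequences):
        part_a, part_b = seq[a0:a1], seq[b0:b1]
        if set(part_a) <= {"-"} or set(part_b) <= {"-"}:
            continue
        seqs.append(part_a + part_b)
        ids.append(sid)
    if not seqs:
        warnings.warn("no sequences cover both interface partners", stacklevel=2)
        return MSA([], [])
    out = MSA(seqs, ids)
    out.blocks = [(0, a1 - a0), (a1 - a0, (a1 - a0) + (b1 - b0))]
    return out


def _pairwise_identity(a: np.ndarray, b: np.ndarray, min_common: int = 10) -> float:
    both = (a != b"-"[0]) & (b != b"-"[0])
    n = int(both.sum())
    if n < min_common:
        return 0.0
    return float((a[both] == b[both]).sum() / n)


def neff(msa: MSA, identity_threshold: float = 0.8) -> float:
    """Effective sequence count: sum over rows of 1/n_i, where n_i counts
    the rows (including i) with pairwise identity >= threshold to row i.

    Identity is computed over columns non-gap in both rows; rows sharing
    fewer than 10 non-gap columns are treated as dissimilar.
    """
    if len(msa) == 0:
        raise ValueError("empty MSA")
    rows = [np.frombuffer(s.encode(), dtype=np.uint8) for s in msa.sequences]
    n = len(rows)
    counts = np.ones(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _pairwise_identity(rows[i], rows[j]) >= identity_threshold:
                counts[i] += 1
                counts[j] += 1
    return float(np.sum(1.0 / counts))


def complex_features(a: Assembly) -> tuple[int, dict[tuple[str, str], int]]:
    """(total residue count, per-interface inter-chain contact counts)."""
    contact_counts = {
        iface.chains: iface.n_contacts
        for iface in extract_interfaces(find_contacts(a))
    }
    return a.n_residues(), contact_counts
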