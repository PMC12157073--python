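"""From raw cytosine-report rows to labeled sites.

The pipeline is: call the sequence context (CpG / CHG / CHH, H = A, C or T)
for every cytosine directly from the genome, apply the minimum-depth filter
(sites with fewer than ``min_depth`` reads become NA), round the methylation
rate to a binary label, and partition sites into train/validation/test sets
by whole chromosomes so evaluation is always on unseen sequence.

Labels use round-half-up on the input side (rate >= 0.5 -> methylated);
prediction-side binarization uses the strict > 0.5 rule and lives in
:mod:`methynet.models`.  Both conventions are deliberate and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COMPLEMENT_CODES, GenomeSequence, N_CODE

__all__ = [
    "CONTEXTS", "INDETERMINATE", "DEFAULT_MIN_DEPTH",
    "CytosineRecord", "SplitSpec", "Splits",
    "call_context", "genome_cytosines", "label_site", "label_sites",
    "prepare_sites", "split_sites", "max_neighbor_gap",
]

CONTEXTS = ("CpG", "CHG", "CHH")
#: Context value for sites whose triplet window contains N or leaves the
#: chromosome; such sites are never used as model targets.
INDETERMINATE = "indeterminate"
#: Minimum aligned reads for a site to receive an observed label.
DEFAULT_MIN_DEPTH = 4

_A, _T, _G, _C = 0, 1, 2, 3


@dataclass
class CytosineRecord:
    """One cytosine site with its observed evidence and label."""

    chrom: str
    pos: int          # 1-based
    strand: str
    context: str
    n_meth: int = 0
    n_unmeth: int = 0
    label: float | None = None   # 1.0 / 0.0 / None for NA

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def rate(self) -> float | None:
        return self.n_meth / self.depth if self.depth > 0 else None


def _oriented_base(codes: np.ndarray, idx0: np.ndarray, minus: np.ndarray,
                   offset: int) -> np.ndarray:
    """Base code at `offset` steps downstream in reading orientation.

    Plus-strand reading moves right on the reference; minus-strand reading
    moves left and complements.  Out-of-range positions return the N code.
    """
    pos = np.where(minus, idx0 - offset, idx0 + offset)
    valid = (pos >= 0) & (pos < len(codes))
    base = np.full(pos.shape, N_CODE, dtype=np.uint8)
    base[valid] = codes[pos[valid]]
    base = np.where(minus, COMPLEMENT_CODES[base], base)
    return base


def _classify(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Map downstream bases (b1, b2) to context indices.

    Returns 0=CpG, 1=CHG, 2=CHH, 3=indeterminate.  CpG is decided by b1
    alone; H = {A, C, T}.
    """
    out = np.full(b1.shape, 3, dtype=np.int8)
    is_h1 = (b1 != _G) & (b1 != N_CODE)
    is_h2 = (b2 != _G) & (b2 != N_CODE)
    out[b1 == _G] = 0
    out[is_h1 & (b2 == _G)] = 1
    out[is_h1 & is_h2] = 2
    return out


_CTX_NAMES = np.array(list(CONTEXTS) + [INDETERMINATE])


def call_context(genome: GenomeSequence, pos: int, strand: str) -> str | None:
    """Context of the cytosine at 1-based ``pos`` on ``strand``.

    Returns ``"CpG"``, ``"CHG"`` or ``"CHH"``; :data:`INDETERMINATE` when the
    triplet window contains N or runs off the chromosome end; ``None`` when
    the base at ``pos`` is not a cytosine in reading orientation.
    """
    if not 1 <= pos <= genome.length:
        raise ValueError(f"position {pos} outside {genome.name} (1..{genome.length})")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    idx0 = np.array([pos - 1])
    minus = np.array([strand == "-"])
    if _oriented_base(genome.codes, idx0, minus, 0)[0] != _C:
        return None
    b1 = _oriented_base(genome.codes, idx0, minus, 1)
    b2 = _oriented_base(genome.codes, idx0, minus, 2)
    return str(_CTX_NAMES[_classify(b1, b2)[0]])


def genome_cytosines(genome: GenomeSequence) -> pd.DataFrame:
    """All cytosines on both strands with their contexts, sorted by position.

    A plus-strand cytosine is a reference C; a minus-strand cytosine is a
    reference G (C on the reverse complement).
    """
    codes = genome.codes
    plus = np.flatnonzero(codes == _C)
    minus = np.flatnonzero(codes == _G)
    idx0 = np.concatenate([plus, minus])
    is_minus = np.concatenate([np.zeros(len(plus), bool), np.ones(len(minus), bool)])
    b1 = _oriented_base(codes, idx0, is_minus, 1)
    b2 = _oriented_base(codes, idx0, is_minus, 2)
    ctx = _CTX_NAMES[_classify(b1, b2)]
    df = pd.DataFrame({
        "chrom": genome.name,
        "pos": idx0 + 1,
        "strand": np.where(is_minus, "-", "+"),
        "context": ctx,
    })
    return df.sort_values("pos", kind="mergesort").reset_index(drop=True)


def label_site(row, min_depth: int = DEFAULT_MIN_DEPTH) -> CytosineRecord:
    """Label one report row: NA below ``min_depth`` reads, else round-half-up."""
    n_meth, n_unmeth = int(row["n_meth"]), int(row["n_unmeth"])
    if n_meth < 0 or n_unmeth < 0:
        raise ValueError("negative read counts")
    depth = n_meth + n_unmeth
    if depth < min_depth:
        label = None
    else:
        label = 1.0 if n_meth / depth >= 0.5 else 0.0
    return CytosineRecord(chrom=row["chrom"], pos=int(row["pos"]),
                          strand=row["strand"],
                          context=row.get("context") or INDETERMINATE,
                          n_meth=n_meth, n_unmeth=n_unmeth, label=label)


def label_sites(report: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Vectorized labeling: adds ``depth``, ``rate`` and ``label`` columns.

    ``label`` is float with NaN for NA sites (depth < ``min_depth``).
    """
    df = report.copy()
    depth = df["n_meth"].to_numpy() + df["n_unmeth"].to_numpy()
    rate = np.divide(df["n_meth"].to_numpy(), depth,
                     out=np.full(len(df), np.nan), where=depth > 0)
    label = np.where(rate >= 0.5, 1.0, 0.0)
    label[depth < min_depth] = np.nan
    df["depth"] = depth
    df["rate"] = rate
    df["label"] = label
    return df


def prepare_sites(report: pd.DataFrame, genomes: dict[str, GenomeSequence],
                  min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Join report rows onto the genome: recompute contexts, apply labels.

    Context is always recomputed from the genome; when the report supplies
    its own context column the number of disagreements is reported as a
    warning (``df.attrs['context_mismatches']``) and the recomputed value
    wins.  Rows at positions that are not cytosines on the claimed strand
    get :data:`INDETERMINATE` context and an NA label.
    """
    parts = []
    mismatches = 0
    for chrom, grp in report.groupby("chrom", sort=True):
        if chrom not in genomes:
            raise KeyError(f"chromosome {chrom!r} in report but not in genome")
        genome = genomes[chrom]
        idx0 = grp["pos"].to_numpy() - 1
        if (idx0 < 0).any() or (idx0 >= genome.length).any():
            raise ValueError(f"report position outside chromosome {chrom}")
        minus = grp["strand"].to_numpy() == "-"
        b0 = _oriented_base(genome.codes, idx0, minus, 0)
        b1 = _oriented_base(genome.codes, idx0, minus, 1)
        b2 = _oriented_base(genome.codes, idx0, minus, 2)
        ctx = _CTX_NAMES[_classify(b1, b2)].copy()
        ctx[b0 != _C] = INDETERMINATE
        grp = grp.copy()
        if grp["context"].notna().any():
            known = grp["context"].notna().to_numpy()
            mismatches += int((grp["context"].to_numpy()[known] != ctx[known]).sum())
        grp["context"] = ctx
        parts.append(grp)
    df = pd.concat(parts, ignore_index=True)
    df = label_sites(df, min_depth=min_depth)
    df.loc[df["context"] == INDETERMINATE, "label"] = np.nan
    if mismatches:
        warnings.warn(f"{mismatches} report context values disagreed with the "
                      "genome; recomputed contexts were used")
    df.attrs["context_mismatches"] = mismatches
    return df


@dataclass
class SplitSpec:
    """Chromosome-holdout split: pairwise-disjoint chromosome sets."""

    train_chroms: frozenset = field(default_factory=frozenset)
    val_chroms: frozenset = field(default_factory=frozenset)
    test_chroms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.train_chroms = frozenset(self.train_chroms)
        self.val_chroms = frozenset(self.val_chroms)
        self.test_chroms = frozenset(self.test_chroms)
        for a, b in (("train", "val"), ("train", "test"), ("val", "test")):
            overlap = getattr(self, f"{a}_chroms") & getattr(self, f"{b}_chroms")
            if overlap:
                raise ValueError(f"{a}/{b} chromosome sets overlap: {sorted(overlap)}")


@dataclass
class Splits:
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    universe: pd.DataFrame   # all sites incl. NA, for imputation


def split_sites(sites: pd.DataFrame, spec: SplitSpec) -> Splits:
    """Partition labeled (non-NA) sites by chromosome.

    NA-labeled sites are excluded from the three model subsets but retained
    in ``universe`` — they are the imputation targets.
    """
    present = set(sites["chrom"].unique())
    for name in ("train", "val", "test"):
        missing = getattr(spec, f"{name}_chroms") - present
        if missing:
            raise ValueError(f"{name} chromosomes not in data: {sorted(missing)}")
    labeled = sites[sites["label"].notna()]
    subsets = {}
    for name in ("train", "val", "test"):
        chroms = getattr(spec, f"{name}_chroms")
        subsets[name] = labeled[labeled["chrom"].isin(chroms)].reset_index(drop=True)
        if len(subsets[name]) == 0:
            warnings.warn(f"{name} split is empty")
    return Splits(train=subsets["train"], val=subsets["val"],
                  test=subsets["test"], universe=sites.reset_index(drop=True))


def max_neighbor_gap(sites: pd.DataFrame) -> int:
    """Largest gap between consecutive cytosine positions, over all chromosomes.

    Computed over every cytosine regardless of context or NA status (site
    positions are known even when states are not); the value normalizes
    neighbor distances into [0, 1] and is stored with trained models.
    """
    best = 0
    any_pair = False
    for _, grp in sites.groupby("chrom"):
        pos = np.unique(grp["pos"].to_numpy())
        if len(pos) >= 2:
            any_pair = True
            best = max(best, int(np.diff(pos).max()))
    if not any_pair:
        raise ValueError("need at least two cytosines on some chromosome")
    return best
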