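"""Model-ready tensors: one-hot sequence windows and neighbor-state vectors.

Two feature families feed the models:

* a one-hot encoded DNA window of 1001 bp centered on the target cytosine
  (500 bp each side), channel order A, T, G, C; minus-strand targets are
  encoded from the reverse complement so the model always sees a centered C;
  off-chromosome positions and N bases become all-zero rows;

* a 100-dimensional neighbor vector for the 25 nearest labeled cytosines on
  each side: 50 state slots followed by 50 distance slots, both in genomic
  (left-to-right) order.  Distances are |pos_n - pos_t| / D_max clipped to 1,
  where D_max is the largest consecutive-cytosine gap in the genome.
  Missing neighbors (chromosome edges, too few labeled sites) pad with
  state 0.5 and distance 1.0 — the maximally uninformative values.

This module is the single place where 1-based external coordinates become
0-based array indices.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import BASE_ORDER, COMPLEMENT_CODES, GenomeSequence, N_CODE

__all__ = [
    "EncodingSpec", "PAD_STATE", "PAD_DISTANCE",
    "one_hot_window", "one_hot_windows", "decode_window",
    "neighbor_features", "neighbor_features_batch",
    "encode_sites", "build_dataset", "save_dataset_cache", "load_dataset_cache",
]

#: Neighbor-slot pad values for absent neighbors.
PAD_STATE = 0.5
PAD_DISTANCE = 1.0

# code -> one-hot row; the N/pad code maps to the all-zero row
_ONE_HOT = np.zeros((5, 4), dtype=np.uint8)
_ONE_HOT[:4] = np.eye(4, dtype=np.uint8)
_C_CODE = 3


@dataclass
class EncodingSpec:
    """Geometry of the feature encodings.

    window_radius : bases each side of the target (window length 2r+1).
    k_neighbors   : labeled neighbor sites per side.
    d_max         : genome-wide normalization length for distances.
    """

    window_radius: int = 500
    k_neighbors: int = 25
    d_max: int | None = None

    @property
    def window_length(self) -> int:
        return 2 * self.window_radius + 1

    @property
    def neighbor_dim(self) -> int:
        return 4 * self.k_neighbors

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingSpec":
        return cls(**d)


def _window_codes(genome: GenomeSequence, pos0: np.ndarray, minus: np.ndarray,
                  radius: int) -> np.ndarray:
    """(n, 2r+1) oriented base codes; out-of-range -> N code."""
    offsets = np.arange(-radius, radius + 1)
    idx = np.where(minus[:, None], pos0[:, None] - offsets, pos0[:, None] + offsets)
    valid = (idx >= 0) & (idx < len(genome.codes))
    codes = np.full(idx.shape, N_CODE, dtype=np.uint8)
    codes[valid] = genome.codes[idx[valid]]
    m = minus.nonzero()[0]
    if len(m):
        codes[m] = COMPLEMENT_CODES[codes[m]]
    return codes


def one_hot_windows(genome: GenomeSequence, positions, strands,
                    spec: EncodingSpec) -> np.ndarray:
    """One-hot windows for many sites of one chromosome.

    ``positions`` are 1-based; every site must be a cytosine in reading
    orientation (reference C on '+', reference G on '-').
    Returns ``(n, 2r+1, 4)`` uint8.
    """
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    if (pos0 < 0).any() or (pos0 >= genome.length).any():
        raise ValueError(f"position outside chromosome {genome.name}")
    minus = np.asarray(strands) == "-"
    codes = _window_codes(genome, pos0, minus, spec.window_radius)
    center = codes[:, spec.window_radius]
    if (center != _C_CODE).any():
        bad = int(np.flatnonzero(center != _C_CODE)[0])
        raise ValueError(
            f"site at {genome.name}:{pos0[bad] + 1} ({'-' if minus[bad] else '+'}) "
            "is not a cytosine in reading orientation")
    return _ONE_HOT[codes]


def one_hot_window(genome: GenomeSequence, pos: int, strand: str,
                   spec: EncodingSpec) -> np.ndarray:
    """Single-site version of :func:`one_hot_windows`; returns (2r+1, 4)."""
    return one_hot_windows(genome, [pos], [strand], spec)[0]


def decode_window(window: np.ndarray) -> str:
    """Inverse of one-hot encoding; all-zero rows decode to N."""
    window = np.asarray(window)
    code = np.where(window.sum(axis=1) == 0, N_CODE, window.argmax(axis=1))
    alphabet = BASE_ORDER + "N"
    return "".join(alphabet[c] for c in code)


def neighbor_features_batch(positions, labels, target_positions,
                            spec: EncodingSpec) -> np.ndarray:
    """Neighbor vectors for many targets on one chromosome.

    ``positions``/``labels`` describe the *eligible* neighbor sites: every
    cytosine with a known (non-NA) label, in ascending position order.  A
    target coinciding with an eligible site never uses itself as a neighbor.
    Returns ``(n_targets, 4k)`` float32: 2k state slots then 2k distance
    slots, genomic order.
    """
    if spec.d_max is None or spec.d_max <= 0:
        raise ValueError("EncodingSpec.d_max must be a positive length")
    pos = np.asarray(positions, dtype=np.int64)
    lab = np.asarray(labels, dtype=np.float32)
    if np.isnan(lab).any():
        raise ValueError("eligible neighbor sites must have known labels")
    if len(pos) > 1 and (np.diff(pos) <= 0).any():
        raise ValueError("neighbor positions must be strictly increasing")
    tgt = np.asarray(target_positions, dtype=np.int64)
    k = spec.k_neighbors
    n = len(tgt)
    if len(pos) == 0:
        out = np.empty((n, 4 * k), dtype=np.float32)
        out[:, : 2 * k] = PAD_STATE
        out[:, 2 * k :] = PAD_DISTANCE
        return out

    right_start = np.searchsorted(pos, tgt, side="left")
    # skip the target itself when it is an eligible site
    self_hit = (right_start < len(pos)) & (pos[np.minimum(right_start, len(pos) - 1)] == tgt)
    right_first = right_start + self_hit

    offsets = np.arange(k)
    left_idx = right_start[:, None] - k + offsets[None, :]     # genomic order, nearest last
    right_idx = right_first[:, None] + offsets[None, :]        # nearest first
    idx = np.concatenate([left_idx, right_idx], axis=1)        # (n, 2k)
    valid = (idx >= 0) & (idx < len(pos))
    idx_c = np.clip(idx, 0, max(len(pos) - 1, 0))

    states = np.where(valid, lab[idx_c], PAD_STATE).astype(np.float32)
    dist = np.abs(pos[idx_c] - tgt[:, None]) / float(spec.d_max)
    dist = np.where(valid, np.minimum(dist, 1.0), PAD_DISTANCE).astype(np.float32)
    return np.concatenate([states, dist], axis=1).reshape(n, 4 * k)


def neighbor_features(positions, labels, target_index: int,
                      spec: EncodingSpec) -> np.ndarray:
    """Neighbor vector for one site *within* a labeled-site array.

    ``target_index`` points into ``positions``; the target's own label may be
    NA (imputation targets), but every other NA site must already have been
    filtered out of ``positions``.
    """
    pos = np.asarray(positions, dtype=np.int64)
    lab = np.asarray(labels, dtype=np.float64)
    keep = np.ones(len(pos), dtype=bool)
    keep[target_index] = False
    known = keep & ~np.isnan(lab)
    return neighbor_features_batch(pos[known], lab[known],
                                   [pos[target_index]], spec)[0]


def encode_sites(sites: pd.DataFrame, genomes: dict[str, GenomeSequence],
                 spec: EncodingSpec,
                 neighbor_sources: pd.DataFrame | None = None,
                 require_labels: bool = True):
    """Encode a site table into model-ready arrays.

    Parameters
    ----------
    sites : target sites (one row per example).
    genomes : chromosome name -> sequence.
    neighbor_sources : sites eligible as neighbors; defaults to the labeled
        rows of ``sites``.  Targets never see themselves as neighbors.
    require_labels : when true (training), NA-labeled targets are an error.

    Returns
    -------
    (seq, nbr, labels) : ``(n, 2r+1, 4)`` uint8, ``(n, 4k)`` float32, and the
    label vector (NaN for NA targets when allowed).  Row order follows
    ``sites``.
    """
    if len(sites) == 0:
        raise ValueError("empty site table")
    labels_all = sites["label"].to_numpy(dtype=np.float64)
    if require_labels and np.isnan(labels_all).any():
        raise ValueError("NA-labeled target in training-example construction")
    if neighbor_sources is None:
        neighbor_sources = sites[sites["label"].notna()]
    seq = np.empty((len(sites), spec.window_length, 4), dtype=np.uint8)
    nbr = np.empty((len(sites), spec.neighbor_dim), dtype=np.float32)
    order = np.arange(len(sites))
    for chrom, grp in sites.groupby("chrom", sort=False):
        if chrom not in genomes:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        rows = grp.index.to_numpy()
        out_rows = order[sites.index.get_indexer(rows)]
        seq[out_rows] = one_hot_windows(
            genomes[chrom], grp["pos"].to_numpy(), grp["strand"].to_numpy(), spec)
        src = neighbor_sources[neighbor_sources["chrom"] == chrom]
        src = src.sort_values("pos", kind="mergesort")
        src_pos = src["pos"].to_numpy(dtype=np.int64)
        src_lab = src["label"].to_numpy(dtype=np.float32)
        # a target present among the sources is skipped inside the batch call
        nbr[out_rows] = neighbor_features_batch(src_pos, src_lab,
                                                grp["pos"].to_numpy(), spec)
    return seq, nbr, labels_all


def build_dataset(sites: pd.DataFrame, genomes: dict[str, GenomeSequence],
                  spec: EncodingSpec, batch_size: int = 128, seed: int = 0,
                  require_labels: bool = True):
    """Yield shuffled batches ``(seq, nbr, labels, site_rows)``.

    Order is deterministic under a fixed seed; ``site_rows`` carries the
    positional indices into ``sites`` for back-reference.
    """
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    seq, nbr, labels = encode_sites(sites, genomes, spec,
                                    require_labels=require_labels)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    for s in range(0, len(order), batch_size):
        idx = order[s : s + batch_size]
        yield seq[idx], nbr[idx], labels[idx], idx


def save_dataset_cache(path, seq, nbr, labels, coords: pd.DataFrame | None = None,
                       group: str = "data") -> None:
    """Cache encoded tensors to HDF5 (uint8 seq, float32 nbr, float labels)."""
    import h5py

    with h5py.File(path, "a") as h5:
        if group in h5:
            del h5[group]
        g = h5.create_group(group)
        g.create_dataset("seq", data=np.asarray(seq, dtype=np.uint8),
                         compression="gzip")
        g.create_dataset("nbr", data=np.asarray(nbr, dtype=np.float32))
        g.create_dataset("label", data=np.asarray(labels, dtype=np.float32))
        if coords is not None:
            g.create_dataset("chrom", data=coords["chrom"].astype(str).to_numpy(),
                             dtype=h5py.string_dtype())
            g.create_dataset("pos", data=coords["pos"].to_numpy(dtype=np.int64))


def load_dataset_cache(path, group: str = "data"):
    import h5py

    with h5py.File(path, "r") as h5:
        g = h5[group]
        return g["seq"][...], g["nbr"][...], g["label"][...]
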