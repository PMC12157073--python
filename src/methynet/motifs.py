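"""Motif extraction from the DNA model's first convolutional layer.

Each of the 128 width-11 kernels is read out as a candidate sequence motif:
kernel activations are scanned over a set of windows; for every (window,
filter) pair the best-activating position contributes its 11-mer iff that
activation exceeds half of the filter's global maximum; the collected
11-mers become a position weight matrix.  Per-filter mean activity over
windows ("occurrence frequency"), a signed effect on the methylation label
(Pearson correlation of activity with labels), and a 2-D PCA embedding of
the activity table complete the readout.

PWM columns are ordered A, C, G, T (the conventional PWM/MEME order;
distinct from the model's A, T, G, C one-hot channel order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .io import BASE_ORDER

__all__ = [
    "Motif", "MotifSet", "ActivityTable",
    "filter_activations", "select_windows", "build_pwm",
    "motif_activity", "motif_effect", "pca_motifs", "extract_motifs",
    "consensus_pwm", "pwm_match_correlation",
]

PWM_ALPHABET = "ACGT"
MOTIF_WIDTH_DEFAULT = 11


@dataclass
class Motif:
    filter_index: int
    pwm: np.ndarray                  # (width, 4), columns A,C,G,T, rows sum to 1
    n_windows: int
    ic: float                        # information content, bits
    effect: float = float("nan")
    pca_xy: tuple = (float("nan"), float("nan"))

    @property
    def consensus(self) -> str:
        return "".join(PWM_ALPHABET[i] for i in self.pwm.argmax(axis=1))


@dataclass
class ActivityTable:
    """Per-filter, per-window activation summaries (filters x windows)."""

    mean: np.ndarray
    max: np.ndarray
    labels: np.ndarray | None = None

    @property
    def shape(self):
        return self.mean.shape


@dataclass
class MotifSet:
    motifs: list[Motif]
    activity: ActivityTable | None = None

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "filter": m.filter_index, "consensus": m.consensus,
            "n_windows": m.n_windows, "ic": m.ic, "effect": m.effect,
            "pc1": m.pca_xy[0], "pc2": m.pca_xy[1],
        } for m in self.motifs])


def _conv1_of(model):
    kind = getattr(model, "model_kind", None)
    if kind == "dna":
        return model.net_.body.layers[0]
    if kind == "joint":
        return model.net_.dna.layers[0]
    raise ValueError("first-layer activations exist only for DNA/joint models")


def filter_activations(model, windows: np.ndarray) -> np.ndarray:
    """Post-ReLU first-convolution activations, shape (n_windows, P, filters).

    ``P = L - kernel + 1`` valid positions: positions whose receptive field
    would cross the window boundary are never produced ('valid' convolution).
    """
    conv = _conv1_of(model)
    windows = np.asarray(windows, dtype=np.float32)
    if windows.ndim != 3 or windows.shape[2] != 4:
        raise ValueError(f"expected (n, L, 4) one-hot windows, got {windows.shape}")
    if windows.shape[0] == 0:
        raise ValueError("need at least one window")
    out = np.empty((windows.shape[0], windows.shape[1] - conv.k + 1, conv.c_out),
                   dtype=np.float32)
    for s in range(0, windows.shape[0], 256):
        out[s:s + 256] = np.maximum(conv.forward(windows[s:s + 256]), 0.0)
    return out


def _decode_kmers(windows: np.ndarray, rows, positions, width) -> list[str]:
    """11-mers from one-hot windows; all-zero rows decode to N."""
    alphabet = BASE_ORDER + "N"
    kmers = []
    for r, p in zip(rows, positions):
        sub = windows[r, p : p + width]
        code = np.where(sub.sum(axis=1) == 0, 4, sub.argmax(axis=1))
        kmers.append("".join(alphabet[c] for c in code))
    return kmers


def select_windows(activations: np.ndarray, windows: np.ndarray,
                   fraction: float = 0.5) -> list[list[str]]:
    """Best-activating 11-mer per (window, filter), above the global bar.

    For filter f the bar is ``fraction`` times its maximum activation across
    *all* windows and positions; each window contributes at most one 11-mer —
    the one at its own best position — and only if that activation strictly
    exceeds the bar.  Subsequences containing N are discarded (they cannot
    enter a PWM).

    Returns one list of 11-mers per filter.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    acts = np.asarray(activations)
    n_win, n_pos, n_filt = acts.shape
    width = windows.shape[1] - n_pos + 1
    global_max = acts.max(axis=(0, 1))              # per filter
    best_pos = acts.argmax(axis=1)                   # (n_win, n_filt)
    best_val = np.take_along_axis(acts, best_pos[:, None, :], axis=1)[:, 0, :]
    selected: list[list[str]] = []
    for f in range(n_filt):
        bar = fraction * global_max[f]
        rows = np.flatnonzero(best_val[:, f] > bar)
        kmers = _decode_kmers(windows, rows, best_pos[rows, f], width)
        selected.append([k for k in kmers if "N" not in k])
    return selected


def build_pwm(subsequences, pseudocount: float = 0.5,
              width: int = MOTIF_WIDTH_DEFAULT):
    """Counts + pseudocount, row-normalized; returns (pwm, ic_bits).

    The contributing 11-mers are position-aligned by construction (each is
    centered on its filter's best activation), so no multiple alignment is
    needed.  An empty list yields the uniform PWM with zero information.
    """
    counts = np.zeros((width, 4), dtype=np.float64)
    n = 0
    for s in subsequences:
        if len(s) != width:
            raise ValueError(f"subsequence {s!r} is not length {width}")
        for i, b in enumerate(s.upper()):
            j = PWM_ALPHABET.find(b)
            if j < 0:
                raise ValueError(f"non-ACGT symbol {b!r} in {s!r}")
            counts[i, j] += 1
        n += 1
    if n == 0 and pseudocount == 0:
        pwm = np.full((width, 4), 0.25)
    else:
        pwm = (counts + pseudocount) / (n + 4.0 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    ic = float(np.sum(2.0 + plogp.sum(axis=1)))
    if n == 0:
        ic = 0.0
    return pwm, ic


def motif_activity(activations: np.ndarray,
                   labels: np.ndarray | None = None) -> ActivityTable:
    """Mean (and max) activation of each filter on each window.

    Output matrices are (filters x windows), matching the convention that
    motifs are observations and windows are features downstream.
    """
    acts = np.asarray(activations)
    return ActivityTable(mean=acts.mean(axis=1).T.copy(),
                         max=acts.max(axis=1).T.copy(),
                         labels=None if labels is None else np.asarray(labels))


def motif_effect(activity: ActivityTable, labels=None) -> np.ndarray:
    """Signed per-filter effect: Pearson r between mean activity and labels.

    A filter whose activity has zero variance carries no information and
    gets effect exactly 0.  Requires both classes present.
    """
    labels = activity.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("labels required for effect estimation")
    y = labels.astype(np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to estimate effects")
    A = activity.mean.astype(np.float64)
    yc = y - y.mean()
    ac = A - A.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac * ac).sum(axis=1) * (yc * yc).sum())
    num = ac @ yc
    out = np.zeros(A.shape[0])
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    return out


def pca_motifs(activity: ActivityTable, scale: bool = False,
               n_components: int = 2) -> np.ndarray:
    """Project filters onto the top-2 principal axes of the activity table.

    Rows (points) are filters, columns (features) are windows; features are
    centered, and optionally unit-scaled.  The sign of each axis is fixed so
    its largest-magnitude loading is positive, making coordinates
    reproducible across runs.
    """
    A = activity.mean.astype(np.float64)
    if A.shape[0] < 3:
        raise ValueError("need at least 3 filters for a PCA projection")
    if scale:
        sd = A.std(axis=0)
        A = A / np.where(sd > 0, sd, 1.0)
    if np.linalg.matrix_rank(A - A.mean(axis=0)) < 2:
        raise ValueError("activity table has fewer than 2 informative dimensions")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(A)
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    return coords


def consensus_pwm(consensus: str, background: float = 0.0) -> np.ndarray:
    """One-hot-like PWM (width x 4, columns A,C,G,T) for a consensus string.

    With ``background`` > 0 the off-consensus entries share that probability
    mass (rows still sum to 1).
    """
    w = len(consensus)
    pwm = np.full((w, 4), background / 3.0 if background else 0.0)
    for i, b in enumerate(consensus.upper()):
        j = PWM_ALPHABET.find(b)
        if j < 0:
            raise ValueError(f"non-ACGT symbol {b!r}")
        pwm[i] = background / 3.0
        pwm[i, j] = 1.0 - background
    return pwm


def _revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    # reverse positions; swap A<->T and C<->G columns (A,C,G,T order)
    return pwm[::-1, [3, 2, 1, 0]]


def pwm_match_correlation(pwm: np.ndarray, consensus: str,
                          max_shift: int = 5) -> float:
    """How well a learned PWM matches a planted consensus.

    Pearson correlation over all matrix entries, maximized over relative
    offsets up to ``max_shift`` (out-of-overlap positions padded with the
    uniform 0.25 row) and over the reverse complement — a filter may learn a
    motif off-center or on the opposite strand.
    """
    target = consensus_pwm(consensus)
    w = target.shape[0]
    best = -1.0
    for cand in (np.asarray(pwm, dtype=float), _revcomp_pwm(np.asarray(pwm, dtype=float))):
        for shift in range(-max_shift, max_shift + 1):
            a = np.full((w, 4), 0.25)
            lo, hi = max(0, shift), min(w, w + shift)
            a[lo:hi] = cand[lo - shift : hi - shift]
            va, vt = a.ravel(), target.ravel()
            va = va - va.mean()
            vt = vt - vt.mean()
            denom = np.sqrt((va * va).sum() * (vt * vt).sum())
            if denom > 0:
                best = max(best, float(va @ vt / denom))
    return best


def extract_motifs(model, windows: np.ndarray, labels=None,
                   fraction: float = 0.5, pseudocount: float = 0.5) -> MotifSet:
    """Full readout: activations -> selection -> PWMs -> activity/effect/PCA."""
    acts = filter_activations(model, windows)
    width = _conv1_of(model).k
    selected = select_windows(acts, windows, fraction=fraction)
    activity = motif_activity(acts, labels=labels)
    effects = (motif_effect(activity) if labels is not None
               else np.full(len(selected), np.nan))
    try:
        coords = pca_motifs(activity)
    except ValueError:
        coords = np.full((len(selected), 2), np.nan)
    motifs = []
    for f, kmers in enumerate(selected):
        pwm, ic = build_pwm(kmers, pseudocount=pseudocount, width=width)
        motifs.append(Motif(filter_index=f, pwm=pwm, n_windows=len(kmers),
                            ic=ic, effect=float(effects[f]),
                            pca_xy=(float(coords[f, 0]), float(coords[f, 1]))))
    return MotifSet(motifs=motifs, activity=activity)
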