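"""Synthetic genomes and methylomes with the structure the models exploit.

The generator mirrors the two signal sources the classifiers read:

* **sequence signal** — consensus motifs stamped into an i.i.d. background
  genome raise (hyper-methylating, positive effect) or lower
  (hypo-methylating, negative effect) the methylation propensity of cytosines
  within ``motif_effect_radius`` of an occurrence;
* **spatial signal** — a latent AR(1) field over consecutive cytosines
  creates the neighbor-state autocorrelation real methylomes show.

For cytosine ``i``: ``z_i = b0 + sum_m beta_m * [occurrence of m within
radius] + u_i`` with ``u`` a stationary AR(1) field (autocorrelation
``spatial_rho``, marginal sd ``spatial_sd``); the true state is
``s_i ~ Bernoulli(logistic(z_i))``.  Read depth is Poisson with a
``low_depth_fraction`` share of sites forced below the 4-read threshold
(these become the NA imputation targets), and methylated read counts are
binomial with a 10% per-read call-error rate, so observed labels are
imperfect and perfect classification is impossible by construction.

Defaults emulate the study conditions: three cytosine contexts on both
strands, ~1:9 methylated:unmethylated imbalance (use
:func:`calibrate_baseline` to pin the ratio), Arabidopsis-like 36% GC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import GenomeSequence, write_cytosine_report, write_fasta
from .preprocess import genome_cytosines

__all__ = [
    "PlantedMotif", "SimConfig", "Simulation",
    "simulate_genome", "simulate_methylome", "simulate",
    "calibrate_baseline", "export_fixture",
]


@dataclass
class PlantedMotif:
    """A consensus string stamped into the genome with a methylation effect.

    ``effect`` is the additive logit shift for cytosines near an occurrence;
    ``density_per_kb`` the expected number of occurrences per kilobase.
    """

    consensus: str
    effect: float
    density_per_kb: float

    def __post_init__(self):
        self.consensus = self.consensus.upper()
        if not set(self.consensus) <= set("ACGT"):
            raise ValueError("motif consensus must be over ACGT")


def _default_motifs():
    # AT-rich hyper-methylating and CG-rich hypo-methylating consensus, the
    # directional pattern plant methylomes show around promoters vs TE bodies
    return [
        PlantedMotif("AATTATTTAAT", +4.0, 0.25),
        PlantedMotif("GCCGCGTCGGC", -4.0, 0.25),
    ]


@dataclass
class SimConfig:
    n_chroms: int = 5
    chrom_length: int = 40_000
    gc_content: float = 0.36
    planted_motifs: list[PlantedMotif] = field(default_factory=_default_motifs)
    baseline_logit: float = -2.9
    spatial_rho: float = 0.99
    spatial_sd: float = 2.5
    motif_effect_radius: int = 500
    depth_lambda: float = 20.0
    low_depth_fraction: float = 0.15
    call_error: float = 0.1
    cpg_symmetric: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_content", "spatial_rho", "low_depth_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.chrom_length <= 2 * 501:
            raise ValueError("chromosomes must be longer than one model window")
        self.planted_motifs = [
            m if isinstance(m, PlantedMotif) else PlantedMotif(*m)
            for m in self.planted_motifs
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_motifs"] = [asdict(m) for m in self.planted_motifs]
        return d


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Background genome plus motif stamps.

    Returns ``(genomes, motif_log)`` where the log has one row per stamp
    (chrom, 1-based start/end, motif index, consensus).  Stamps never
    overlap; every stamp is recorded.
    """
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])  # A,T,G,C
    genomes: dict[str, GenomeSequence] = {}
    log_rows = []
    for ci in range(config.n_chroms):
        name = f"chr{ci + 1}"
        codes = rng.choice(4, size=config.chrom_length, p=base_p).astype(np.uint8)
        occupied = np.zeros(config.chrom_length, dtype=bool)
        for mi, motif in enumerate(config.planted_motifs):
            w = len(motif.consensus)
            if w > config.chrom_length:
                raise ValueError("motif longer than chromosome")
            n_stamps = rng.poisson(motif.density_per_kb * config.chrom_length / 1000.0)
            starts = np.sort(rng.integers(0, config.chrom_length - w + 1,
                                          size=n_stamps))
            mcodes = np.array(["ATGC".index(b) for b in motif.consensus],
                              dtype=np.uint8)
            for s in starts:
                if occupied[s : s + w].any():
                    continue
                codes[s : s + w] = mcodes
                occupied[s : s + w] = True
                log_rows.append({"chrom": name, "start": int(s) + 1,
                                 "end": int(s) + w, "motif_index": mi,
                                 "consensus": motif.consensus})
        genomes[name] = GenomeSequence(name, "".join("ATGC"[c] for c in codes))
    motif_log = pd.DataFrame(log_rows, columns=["chrom", "start", "end",
                                                "motif_index", "consensus"])
    return genomes, motif_log


def _motif_indicator(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                     radius: int) -> np.ndarray:
    """True where a site lies within ``radius`` of an occurrence footprint."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    lo = starts - radius
    hi = ends + radius
    # merge overlapping effect intervals, then interval-stab each position
    order = np.argsort(lo)
    lo, hi = lo[order], hi[order]
    merged_lo, merged_hi = [lo[0]], [hi[0]]
    for a, b in zip(lo[1:], hi[1:]):
        if a <= merged_hi[-1]:
            merged_hi[-1] = max(merged_hi[-1], b)
        else:
            merged_lo.append(a)
            merged_hi.append(b)
    merged_lo = np.asarray(merged_lo)
    merged_hi = np.asarray(merged_hi)
    k = np.searchsorted(merged_lo, pos, side="right") - 1
    k = np.clip(k, 0, len(merged_lo) - 1)
    return (pos >= merged_lo[k]) & (pos <= merged_hi[k])


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sample of length n with marginal sd ``sd``."""
    if n == 0:
        return np.empty(0)
    e = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho * rho)
    e[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -rho], e)


@dataclass
class Simulation:
    config: SimConfig
    genomes: dict
    motif_log: pd.DataFrame
    report: pd.DataFrame
    truth: pd.DataFrame


def simulate_methylome(genomes: dict, motif_log: pd.DataFrame,
                       config: SimConfig,
                       rng: np.random.Generator | None = None):
    """Draw states, depths and read counts for every cytosine (both strands).

    Returns ``(report, truth)``; ``truth`` carries the hidden state of every
    site including the sub-threshold ones, which is what imputation is scored
    against.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    report_parts, truth_parts = [], []
    for name, genome in genomes.items():
        sites = genome_cytosines(genome)
        pos = sites["pos"].to_numpy()
        n = len(sites)
        z = np.full(n, config.baseline_logit, dtype=np.float64)
        for mi, motif in enumerate(config.planted_motifs):
            occ = motif_log[(motif_log["chrom"] == name)
                            & (motif_log["motif_index"] == mi)]
            ind = _motif_indicator(pos, occ["start"].to_numpy(),
                                   occ["end"].to_numpy(),
                                   config.motif_effect_radius)
            z += motif.effect * ind
            sites[f"motif_{mi}"] = ind
        z += _ar1(n, config.spatial_rho, config.spatial_sd, rng)
        p = 1.0 / (1.0 + np.exp(-z))
        s = (rng.random(n) < p).astype(np.int8)

        if config.cpg_symmetric:
            # copy the plus-strand state onto the minus-strand partner of a
            # symmetric CpG dyad (C at p paired with G at p+1)
            is_cpg = (sites["context"] == "CpG").to_numpy()
            plus = (sites["strand"] == "+").to_numpy()
            pos_to_row = {(int(pp)): i for i, pp in enumerate(pos)}
            for i in np.flatnonzero(is_cpg & ~plus):
                j = pos_to_row.get(int(pos[i]) - 1)
                if j is not None and is_cpg[j] and plus[j]:
                    s[i] = s[j]

        depth = rng.poisson(config.depth_lambda, size=n)
        low = rng.random(n) < config.low_depth_fraction
        depth[low] = rng.integers(0, 4, size=int(low.sum()))
        p_read = np.where(s == 1, 1.0 - config.call_error, config.call_error)
        n_meth = rng.binomial(depth, p_read)

        report_parts.append(pd.DataFrame({
            "chrom": name, "pos": pos, "strand": sites["strand"],
            "n_meth": n_meth, "n_unmeth": depth - n_meth,
            "context": sites["context"],
        }))
        truth = sites.copy()
        truth["latent"] = z
        truth["true_state"] = s
        truth["depth"] = depth
        truth_parts.append(truth)
    report = pd.concat(report_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    report.attrs["context_present"] = True
    return report, truth


def simulate(config: SimConfig) -> Simulation:
    """Genome + methylome in one call, fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genomes, motif_log = simulate_genome(config, rng)
    report, truth = simulate_methylome(genomes, motif_log, config, rng)
    return Simulation(config=config, genomes=genomes, motif_log=motif_log,
                      report=report, truth=truth)


def calibrate_baseline(config: SimConfig, target: float = 0.1,
                       tol: float = 1e-4, max_iter: int = 60) -> float:
    """Baseline logit that makes the expected methylated fraction ``target``.

    Bisects over the baseline using one sampled realization of the
    non-baseline logit components (motif contributions + AR(1) field) from a
    genome drawn under ``config``; deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genomes, motif_log = simulate_genome(config, rng)
    comps = []
    for name, genome in genomes.items():
        sites = genome_cytosines(genome)
        pos = sites["pos"].to_numpy()
        z = np.zeros(len(sites))
        for mi, motif in enumerate(config.planted_motifs):
            occ = motif_log[(motif_log["chrom"] == name)
                            & (motif_log["motif_index"] == mi)]
            z += motif.effect * _motif_indicator(
                pos, occ["start"].to_numpy(), occ["end"].to_numpy(),
                config.motif_effect_radius)
        z += _ar1(len(sites), config.spatial_rho, config.spatial_sd, rng)
        comps.append(z)
    comp = np.concatenate(comps)
    lo, hi = -20.0, 20.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(1.0 / (1.0 + np.exp(-(mid + comp)))))
        if abs(frac - target) < tol:
            break
        if frac < target:
            lo = mid
        else:
            hi = mid
    return mid


def export_fixture(sim: Simulation, out_dir) -> dict[str, Path]:
    """Write FASTA, cytosine report, hidden-truth TSV and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "report": out / "cytosine_report.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.json",
    }
    write_fasta(sim.genomes, paths["fasta"])
    write_cytosine_report(sim.report, paths["report"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(sim.config.to_dict(), indent=2))
    return paths
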