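"""End-to-end study runners: simulate -> preprocess -> encode -> train -> score.

Three named simulation regimes probe the two model branches:

* :func:`default_study_config` — both signal sources at their default
  strengths (wide-radius motif effects plus a strong AR(1) field); the
  regime every headline number is computed under.
* :func:`spatial_study_config` — no motifs: labels depend only on the
  neighborhood, so the methylation model should dominate the DNA model.
* :func:`motif_study_config` — motif effects with a tight (25 bp) radius,
  no spatial field, and sparse labeled coverage (85% of sites below the
  read-depth threshold), so labeled neighbors are mostly out of reach of
  any occurrence and the sequence branch is the only usable signal.  The
  tight radius and sparse coverage are what make this regime isolate the
  DNA model: a wide effect radius would re-express the sequence signal as
  neighbor-state correlation.

The desk-scale model widths used here (16-32 filters, 16/24-unit GRUs,
501 bp windows, a few thousand training sites) keep a full three-model study
in CPU-minutes; the architectural defaults in :mod:`methynet.models` retain
the full-scale layer sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encode as enc
from . import metrics as met
from . import preprocess as pp
from .impute import impute_genome
from .models import (DnaCnnClassifier, JointMethylationClassifier,
                     NeighborGruClassifier)
from .simulate import PlantedMotif, SimConfig, Simulation, calibrate_baseline, simulate

__all__ = [
    "AT_CONSENSUS", "CG_CONSENSUS", "StudySizes", "StudyResult",
    "default_study_config", "spatial_study_config", "motif_study_config",
    "run_study", "score_imputation",
]

#: Planted consensus strings: AT-rich hyper-methylating, CG-rich
#: hypo-methylating — the directional pattern the motif analysis recovers.
AT_CONSENSUS = "AATTATTTAAT"
CG_CONSENSUS = "GCCGCGTCGGC"


def default_study_config(seed: int = 0) -> SimConfig:
    """Both-signals regime at generator defaults (4 x 40 kb chromosomes)."""
    return SimConfig(n_chroms=4, chrom_length=40_000, seed=seed)


def spatial_study_config(seed: int = 0) -> SimConfig:
    """Neighbor-signal-only regime: AR(1) field, no planted motifs."""
    return SimConfig(n_chroms=4, chrom_length=40_000, planted_motifs=[],
                     seed=seed)


def motif_study_config(seed: int = 0) -> SimConfig:
    """Sequence-signal-only regime: tight-radius motif effects, no field,
    sparse labeled coverage (see module docstring)."""
    return SimConfig(
        n_chroms=4, chrom_length=80_000,
        planted_motifs=[PlantedMotif(AT_CONSENSUS, +4.0, 2.5),
                        PlantedMotif(CG_CONSENSUS, -4.0, 2.5)],
        motif_effect_radius=25, spatial_rho=0.5, spatial_sd=0.0,
        low_depth_fraction=0.85, seed=seed)


@dataclass
class StudySizes:
    """Subsample sizes for the train/val/test chromosomes."""

    n_train: int = 8000
    n_val: int = 1200
    n_test: int = 2000


# training settings for the desk-scale models; architectural widths are
# reduced, everything else matches the full-scale defaults
_DNA_PARAMS = dict(conv1_filters=16, conv2_filters=16, fc_units=32,
                   dropout_rate=0.4, max_epochs=18, patience=5,
                   class_weight="balanced", validation_fraction=0.0)
_DNA_PARAMS_MOTIF = dict(conv1_filters=24, conv2_filters=16, fc_units=32,
                         dropout_rate=0.25, max_epochs=40, patience=8,
                         class_weight="balanced", validation_fraction=0.0)
_METH_PARAMS = dict(td_units=8, gru1_units=16, gru2_units=24,
                    max_epochs=60, patience=8, validation_fraction=0.0)
_JOINT_PARAMS = dict(joint_units=64, learning_rate=3e-4, max_epochs=12,
                     patience=4, validation_fraction=0.0)


@dataclass
class StudyResult:
    config: SimConfig
    sim: Simulation
    sites: pd.DataFrame
    splits: pp.Splits
    spec: enc.EncodingSpec
    data: dict                      # split -> (seq, nbr, labels)
    models: dict = field(default_factory=dict)
    reports: dict = field(default_factory=dict)   # model kind -> MetricsReport

    def model_input(self, kind: str, split: str):
        seq, nbr, _ = self.data[split]
        return {"dna": seq, "meth": nbr, "joint": (seq, nbr)}[kind]

    def labels(self, split: str):
        return self.data[split][2]


def subsample_sites(df: pd.DataFrame, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if len(df) <= n:
        return df
    keep = np.sort(rng.choice(len(df), size=n, replace=False))
    return df.iloc[keep]


def run_study(config: SimConfig, sizes: StudySizes | None = None,
              which=("dna", "meth", "joint"), window_radius: int = 250,
              calibrate: bool = True, target_fraction: float = 0.1,
              seed: int = 0, verbose: bool = False) -> StudyResult:
    """Simulate a methylome, train the requested models, score the test set.

    Chromosome split: the first half of the chromosomes train, the
    next-to-last validates, the last one tests.  ``seed`` controls
    subsampling and model initialization; the simulation's own seed lives in
    ``config.seed``.
    """
    sizes = sizes or StudySizes()
    if calibrate:
        config.baseline_logit = calibrate_baseline(config, target=target_fraction)
    sim = simulate(config)
    sites = pp.prepare_sites(sim.report, sim.genomes)
    chroms = [g for g in sim.genomes]
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes for a train/val/test split")
    split_spec = pp.SplitSpec(train_chroms=chroms[: len(chroms) - 2],
                              val_chroms={chroms[-2]}, test_chroms={chroms[-1]})
    splits = pp.split_sites(sites, split_spec)
    spec = enc.EncodingSpec(window_radius=window_radius, k_neighbors=25,
                            d_max=pp.max_neighbor_gap(sites))

    rng = np.random.default_rng(seed)
    data = {}
    for name, df, n in (("train", splits.train, sizes.n_train),
                        ("val", splits.val, sizes.n_val),
                        ("test", splits.test, sizes.n_test)):
        data[name] = enc.encode_sites(subsample_sites(df, n, rng), sim.genomes, spec)

    result = StudyResult(config=config, sim=sim, sites=sites, splits=splits,
                         spec=spec, data=data)
    val = {k: (data["val"][0] if k == "dna" else data["val"][1], data["val"][2])
           for k in ("dna", "meth")}
    dna_params = (_DNA_PARAMS_MOTIF if config.low_depth_fraction > 0.5
                  else _DNA_PARAMS)

    if "dna" in which or "joint" in which:
        dna = DnaCnnClassifier(window_radius=window_radius, random_state=seed,
                               **dna_params)
        dna.fit(data["train"][0], data["train"][2],
                validation_data=val["dna"], verbose=verbose)
        dna.set_encoding(spec)
        result.models["dna"] = dna
    if "meth" in which or "joint" in which:
        meth = NeighborGruClassifier(random_state=seed, **_METH_PARAMS)
        meth.fit(data["train"][1], data["train"][2],
                 validation_data=val["meth"], verbose=verbose)
        meth.set_encoding(spec)
        result.models["meth"] = meth
    if "joint" in which:
        joint = JointMethylationClassifier(
            window_radius=window_radius,
            conv1_filters=dna_params["conv1_filters"],
            conv2_filters=dna_params["conv2_filters"],
            fc_units=dna_params["fc_units"],
            td_units=_METH_PARAMS["td_units"],
            gru1_units=_METH_PARAMS["gru1_units"],
            gru2_units=_METH_PARAMS["gru2_units"],
            dropout_rate=dna_params["dropout_rate"],
            random_state=seed,
            warm_start_models=(result.models["dna"], result.models["meth"]),
            **_JOINT_PARAMS)
        joint.fit((data["train"][0], data["train"][1]), data["train"][2],
                  validation_data=((data["val"][0], data["val"][1]),
                                   data["val"][2]), verbose=verbose)
        joint.set_encoding(spec)
        result.models["joint"] = joint

    for kind in which:
        if kind in result.models:
            probs = result.models[kind].predict_probability(
                result.model_input(kind, "test"))
            result.reports[kind] = met.metrics(result.labels("test"), probs)
    return result


def score_imputation(result: StudyResult, kind: str = "joint",
                     max_sites: int = 4000, seed: int = 0):
    """Impute NA sites on the held-out chromosome; score against hidden truth.

    Returns ``(report, table)``: the metric panel of predicted probabilities
    at NA sites versus the simulator's true states, and the methylome table.
    """
    model = result.models[kind]
    test_chrom = result.sim.truth["chrom"].unique()[-1]
    sites = result.sites[result.sites["chrom"] == test_chrom]
    na = sites[sites["label"].isna() & (sites["context"] != pp.INDETERMINATE)]
    rng = np.random.default_rng(seed)
    na = subsample_sites(na, max_sites, rng)
    observed = sites[sites["label"].notna()]
    universe = pd.concat([observed, na]).sort_values("pos").reset_index(drop=True)
    table = impute_genome(model, universe, result.sim.genomes)
    truth = result.sim.truth.set_index(["chrom", "pos"])["true_state"]
    na_rows = table[table["observed_state"].isna()]
    y = truth.loc[list(zip(na_rows["chrom"], na_rows["pos"]))].to_numpy()
    report = met.metrics(y, na_rows["pred_prob"].to_numpy())
    return report, table
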