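"""Genome-wide imputation of NA methylation states from a trained model.

Every site receives a predicted probability; sites whose observed state is
known keep it as the final state (no silent correction), while NA sites —
those under the read-depth threshold — get the binarized prediction
(> 0.5 -> methylated).  Neighbor features for every target are built from
observed-labeled sites only, in a single pass: previously imputed values are
never fed back, so errors cannot compound.  Processing streams one
chromosome at a time.

Sites with indeterminate context (N in the triplet or chromosome edge) are
carried through flagged, with no prediction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .encode import encode_sites
from .models import binarize
from .preprocess import INDETERMINATE

__all__ = ["impute_genome", "region_report"]


def impute_genome(model, sites: pd.DataFrame, genomes: dict,
                  spec=None, batch_rows: int = 8192,
                  overwrite_observed: bool = False) -> pd.DataFrame:
    """Predict probabilities for all sites and fill NA states.

    Parameters
    ----------
    model : a fitted classifier (DNA, methylation or joint); its stored
        ``encoding_spec_`` is used unless ``spec`` overrides it.
    sites : labeled site table (output of ``preprocess.prepare_sites``),
        with NaN labels at the NA sites to fill.
    genomes : chromosome -> GenomeSequence.
    overwrite_observed : when true, observed states are replaced by the
        model's binarized predictions as well.  Off by default: the method
        defines no criterion for calling an observed state inaccurate, so
        observed labels are authoritative.

    Returns the methylome table: one output row per input row, with
    ``pred_prob`` and ``imputed_state`` columns added.
    """
    if spec is None:
        spec = getattr(model, "encoding_spec_", None)
        if spec is None:
            raise ValueError("model carries no EncodingSpec; pass spec=...")
    if spec.d_max is None:
        raise ValueError("EncodingSpec.d_max is unset")
    missing = set(sites["chrom"].unique()) - set(genomes)
    if missing:
        raise KeyError(f"chromosomes in site table but not in genome: "
                       f"{sorted(missing)}")

    out = sites.reset_index(drop=True).copy()
    out["pred_prob"] = np.nan
    predictable = (out["context"] != INDETERMINATE).to_numpy()

    for chrom in out["chrom"].unique():
        cmask = (out["chrom"] == chrom).to_numpy() & predictable
        idx = np.flatnonzero(cmask)
        if len(idx) == 0:
            continue
        chrom_sites = out.iloc[idx]
        observed = chrom_sites[chrom_sites["label"].notna()]
        for s in range(0, len(idx), batch_rows):
            chunk = chrom_sites.iloc[s : s + batch_rows]
            seq, nbr, _ = encode_sites(chunk, {chrom: genomes[chrom]}, spec,
                                       neighbor_sources=observed,
                                       require_labels=False)
            X = _model_input(model, seq, nbr)
            out.loc[out.index[idx[s : s + batch_rows]], "pred_prob"] = \
                model.predict_probability(X)

    observed_state = out["label"].to_numpy(dtype=np.float64)
    imputed = np.where(np.isnan(out["pred_prob"]), np.nan,
                       binarize(np.nan_to_num(out["pred_prob"])).astype(float))
    if overwrite_observed:
        final = imputed
    else:
        final = np.where(np.isnan(observed_state), imputed, observed_state)
    out = out.rename(columns={"label": "observed_state"})
    out["imputed_state"] = final
    out["indeterminate"] = ~predictable
    return out


def _model_input(model, seq, nbr):
    kind = getattr(model, "model_kind", "joint")
    if kind == "dna":
        return seq
    if kind == "meth":
        return nbr
    return (seq, nbr)


def region_report(table: pd.DataFrame, chrom: str, start: int,
                  end: int) -> pd.DataFrame:
    """Observed and imputed state tracks within [start, end] (1-based incl.).

    Returns one row per site in the interval with the columns needed for a
    genome-browser style plot or bedGraph export; an empty interval yields
    an empty frame.
    """
    if end < start:
        raise ValueError("interval end before start")
    mask = (table["chrom"] == chrom) & (table["pos"] >= start) & (table["pos"] <= end)
    cols = ["chrom", "pos", "strand", "context", "observed_state",
            "pred_prob", "imputed_state"]
    return table.loc[mask, cols].reset_index(drop=True)
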