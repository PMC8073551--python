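"""Efficiency-corrected relative quantification of qPCR data.

Raw quantification cycles (Cq) are converted into relative expression with
a Pfaffl-style efficiency correction against the geometric mean of the
reference genes (Rplp0 and ActB by default):

    Q(g, s)  = E_g ** (-Cq(g, s))        per-gene quantity for sample s
    N(s)     = geomean over references r of Q(r, s)
    value(g, s) = Q(g, s) / N(s)

With all efficiencies equal to 2 this reduces to the classic
``2**(-dCq)`` against the reference geometric mean.  Technical-replicate
Cq values are averaged on the Cq scale before quantification.  A sample is
identified by its (condition, experiment, time) coordinates; samples
missing any reference measurement are dropped with a warning.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["DEFAULT_REFERENCE_GENES", "normalize"]

DEFAULT_REFERENCE_GENES = ("Rplp0", "ActB")

_SAMPLE_KEY = ["condition", "experiment", "time_h"]


def _check_efficiencies(genes, efficiencies: Mapping[str, float]) -> None:
    missing = [g for g in genes if g not in efficiencies]
    if missing:
        raise ValidationError(f"missing amplification efficiency for genes: {missing}")
    bad = {g: efficiencies[g] for g in genes
           if not (1.0 < efficiencies[g] <= 2.0)}
    if bad:
        raise ValidationError(
            f"amplification efficiencies must lie in (1, 2]: {bad}")


def normalize(cq: pd.DataFrame, efficiencies: Mapping[str, float],
              reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
              calibrator: Mapping[str, object] | None = None) -> pd.DataFrame:
    """Efficiency-corrected relative expression normalized to reference genes.

    Parameters
    ----------
    cq
        Long-format table with columns ``gene, condition, experiment,
        time_h, cq``.  Technical replicates (duplicate rows per gene and
        sample) are averaged on the Cq scale.
    efficiencies
        Per-gene amplification fold per cycle, each in (1, 2].
    reference_genes
        Genes whose geometric-mean quantity defines the per-sample
        normalization factor; they must be measured in every sample that
        carries target measurements (samples violating this are dropped).
    calibrator
        Optional column->value selection (e.g. ``{"condition": "K",
        "time_h": 2}``); each gene's values are further divided by that
        gene's geometric-mean value over the selected samples.

    Returns
    -------
    pandas.DataFrame
        ExpressionSeries table ``gene, condition, experiment, time_h,
        value`` for the target (non-reference) genes; values are strictly
        positive and dimensionless.
    """
    required = {"gene", *_SAMPLE_KEY, "cq"}
    if not required.issubset(cq.columns):
        raise ValidationError(f"Cq table must have columns {sorted(required)}")
    if not np.all(np.isfinite(cq["cq"])) or (cq["cq"] <= 0).any():
        raise ValidationError("Cq values must be finite and positive")
    genes = cq["gene"].unique()
    refs = [g for g in reference_genes if g in set(genes)]
    if len(refs) < len(reference_genes):
        missing = sorted(set(reference_genes) - set(refs))
        raise ValidationError(f"reference genes absent from Cq table: {missing}")
    _check_efficiencies(genes, efficiencies)

    mean_cq = (cq.groupby(["gene", *_SAMPLE_KEY], as_index=False, sort=False)["cq"]
                 .mean())
    eff = mean_cq["gene"].map(dict(efficiencies)).to_numpy(dtype=float)
    mean_cq["quantity"] = eff ** (-mean_cq["cq"].to_numpy(dtype=float))

    ref_q = mean_cq[mean_cq["gene"].isin(refs)]
    norm = (ref_q.groupby(_SAMPLE_KEY)
                 .agg(n_refs=("gene", "nunique"),
                      log_q=("quantity", lambda q: np.log(q).mean()))
                 .reset_index())
    complete = norm[norm["n_refs"] == len(refs)].copy()
    complete["norm_factor"] = np.exp(complete["log_q"])

    targets = mean_cq[~mean_cq["gene"].isin(refs)]
    target_samples = targets[_SAMPLE_KEY].drop_duplicates()
    dropped = target_samples.merge(complete[_SAMPLE_KEY], on=_SAMPLE_KEY,
                                   how="left", indicator=True)
    dropped = dropped[dropped["_merge"] == "left_only"][_SAMPLE_KEY]
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} sample(s) missing a reference measurement: "
            f"{dropped.to_dict('records')}", stacklevel=2)
    out = targets.merge(complete[_SAMPLE_KEY + ["norm_factor"]],
                        on=_SAMPLE_KEY, how="inner")
    out["value"] = out["quantity"] / out["norm_factor"]

    if calibrator is not None:
        mask = np.ones(len(out), dtype=bool)
        for col, val in calibrator.items():
            if col not in out.columns:
                raise ValidationError(f"calibrator selector column {col!r} not found")
            mask &= (out[col] == val).to_numpy()
        if not mask.any():
            raise ValidationError(f"calibrator selection matched no samples: {calibrator}")
        cal = (out[mask].groupby("gene")["value"]
                        .apply(lambda v: np.exp(np.log(v).mean())))
        missing = sorted(set(out["gene"]) - set(cal.index))
        if missing:
            raise ValidationError(f"calibrator selection lacks genes: {missing}")
        out["value"] = out["value"] / out["gene"].map(cal).to_numpy()

    return (out[["gene", *_SAMPLE_KEY, "value"]]
            .rename(columns={})
            .sort_values(["gene", *_SAMPLE_KEY], ignore_index=True))
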