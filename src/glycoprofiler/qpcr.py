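"""qRT-PCR relative expression: 2^(-dCT) against housekeeping controls.

The relative expression of a gene of interest is 2^(-dCT) with
dCT = CT(target) - CT(controls), assuming primer efficiency 2; the control CT
is the arithmetic mean of the control genes' replicate-mean CTs (EF1a and the
ribosomal protein L21 by default). Primer efficiency is verified from a 1:2
serial dilution row: CT regressed on log2(dilution factor), efficiency
2^(1/slope).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_ct_table",
    "relative_expression",
    "primer_efficiency",
    "DEFAULT_CONTROL_GENES",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTROL_GENES = ("EF1a", "L21")

_REQUIRED = {"gene", "line", "replicate", "ct"}


def validate_ct_table(table: pd.DataFrame,
                      control_genes=DEFAULT_CONTROL_GENES) -> pd.DataFrame:
    """Check a CT table (gene, line, replicate, ct) and warn on non-triplicates."""
    if not _REQUIRED.issubset(table.columns):
        raise ValueError(f"CT table must have columns {sorted(_REQUIRED)}")
    if (table["ct"] <= 0).any():
        raise ValueError("CT values must be > 0")
    if not set(control_genes) & set(table["gene"]):
        raise ValueError("no control gene present in CT table")
    sizes = table.groupby(["gene", "line"], sort=False).size()
    if (sizes != 3).any():
        logger.warning("non-triplicate groups in CT table: %s",
                       sizes[sizes != 3].to_dict())
    return table


def relative_expression(
    table: pd.DataFrame,
    target_gene: str,
    line: str,
    control_genes=DEFAULT_CONTROL_GENES,
) -> dict:
    """2^(-dCT) of ``target_gene`` in ``line``, with SD on the ratio scale.

    dCT is computed per target replicate against the mean-of-controls CT;
    the SD (ddof=1) is taken over the replicate 2^(-dCT) values, matching
    error bars drawn on the ratio scale. Per-control normalizations are also
    returned so the combination rule is auditable.
    """
    validate_ct_table(table, control_genes)
    sub = table[table["line"] == line]
    target_cts = sub.loc[sub["gene"] == target_gene, "ct"].to_numpy(dtype=float)
    if len(target_cts) == 0:
        raise ValueError(f"no CT values for target {target_gene!r} in line {line!r}")
    control_means = []
    for gene in control_genes:
        cts = sub.loc[sub["gene"] == gene, "ct"].to_numpy(dtype=float)
        if len(cts) == 0:
            raise ValueError(f"missing control gene {gene!r} for line {line!r}")
        control_means.append(cts.mean())
    control_ct = float(np.mean(control_means))
    ratios = 2.0 ** (-(target_cts - control_ct))
    per_control = {
        gene: float(np.mean(2.0 ** (-(target_cts - cm))))
        for gene, cm in zip(control_genes, control_means)
    }
    return {
        "expression": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        "n_replicates": len(ratios),
        "control_ct": control_ct,
        "per_control": per_control,
    }


def primer_efficiency(
    dilution_factors: np.ndarray,
    cts: np.ndarray,
    dilution_base: float = 2.0,
) -> dict:
    """Primer efficiency from a serial dilution row.

    Regresses CT on log_base(dilution factor); a perfectly efficient pair
    (efficiency 2 for 1:2 steps) gains exactly one cycle per dilution step.
    Non-monotone CTs warn; a zero slope (constant CTs) is degenerate and
    raises.
    """
    factors = np.asarray(dilution_factors, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if len(factors) < 3:
        raise ValueError("need >= 3 dilution levels")
    x = np.log(factors) / np.log(dilution_base)
    order = np.argsort(x)
    if np.any(np.diff(ct[order]) < 0):
        warnings.warn("CT values are not monotone along the dilution row")
    fit = stats.linregress(x, ct)
    if abs(fit.slope) < 1e-12:
        raise ValueError("zero slope: infinite apparent efficiency")
    return {
        "efficiency": float(dilution_base ** (1.0 / fit.slope)),
        "slope": float(fit.slope),
        "r_squared": float(fit.rvalue) ** 2,
    }
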