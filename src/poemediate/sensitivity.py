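"""Mediational E-value sensitivity analysis.

The E-value of an effect estimate on the risk-ratio scale is the minimum
strength of association (again on the risk-ratio scale) that an unmeasured
mediator-outcome confounder would need to have with *both* the mediator and
the outcome to fully explain away the observed indirect (or direct) effect.
For a rare outcome, odds ratios approximate risk ratios, so odds-ratio
estimates from the mediation decomposition are used directly.

For an estimate RR >= 1 the E-value is RR + sqrt(RR * (RR - 1)); estimates
below 1 are first inverted, making the measure symmetric in x vs 1/x.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import pandas as pd

__all__ = ["EValueResult", "mediational_evalue", "evalue_for_table"]


@dataclass(frozen=True)
class EValueResult:
    input_or: float
    evalue_point: float


def mediational_evalue(or_estimate: float) -> EValueResult:
    """E-value for an odds-ratio estimate under the rare-outcome approximation.

    >>> mediational_evalue(1.0).evalue_point
    1.0
    """
    if not or_estimate > 0:
        raise ValueError(f"odds ratio must be positive, got {or_estimate}")
    rr = or_estimate if or_estimate >= 1.0 else 1.0 / or_estimate
    return EValueResult(input_or=float(or_estimate), evalue_point=rr + sqrt(rr * (rr - 1.0)))


def evalue_for_table(results: pd.DataFrame, or_col: str = "or") -> pd.DataFrame:
    """Append a point E-value column computed from unrounded odds ratios."""
    out = results.copy()
    out["evalue"] = [mediational_evalue(v).evalue_point for v in out[or_col]]
    return out
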