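"""Aggregate per-patient outcomes into the population burden summary."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .parameters import CostTriple


@dataclass(frozen=True)
class BurdenSummary:
    """Population totals, per-case means and percentile intervals for one horizon.

    The interval is the empirical 2.5th-97.5th percentile of the
    patient-level outcome distribution (not a confidence interval of the
    mean), which is why it can be highly skewed around the mean.
    """

    horizon: int | None
    n: int
    total_cost: float
    total_qalys: float
    per_case_cost_mean: float
    per_case_cost_ci: tuple[float, float]
    per_case_qaly_mean: float
    per_case_qaly_ci: tuple[float, float]
    component_means: CostTriple
    per_case_lys_mean: float = float("nan")

    def to_dict(self, usd_per_aud: float | None = None) -> dict:
        d = {
            "horizon": self.horizon,
            "n": self.n,
            "total_cost_aud": self.total_cost,
            "total_qalys": self.total_qalys,
            "per_case_cost_aud": self.per_case_cost_mean,
            "per_case_cost_pct2p5": self.per_case_cost_ci[0],
            "per_case_cost_pct97p5": self.per_case_cost_ci[1],
            "per_case_qalys": self.per_case_qaly_mean,
            "per_case_qalys_pct2p5": self.per_case_qaly_ci[0],
            "per_case_qalys_pct97p5": self.per_case_qaly_ci[1],
            "per_case_medical_aud": self.component_means.medical,
            "per_case_nonmedical_aud": self.component_means.nonmedical,
            "per_case_indirect_aud": self.component_means.indirect,
            "per_case_lys": self.per_case_lys_mean,
        }
        if usd_per_aud is not None:
            for key in list(d):
                if key.endswith("_aud"):
                    d[key.replace("_aud", "_usd")] = to_usd(d[key], usd_per_aud)
        return d

    def to_frame(self, usd_per_aud: float | None = None) -> pd.DataFrame:
        d = self.to_dict(usd_per_aud)
        return pd.DataFrame({"quantity": list(d), "value": list(d.values())})


def summarize(outcomes: pd.DataFrame, horizon: int | None = None) -> BurdenSummary:
    """Means, totals, component breakdown and percentile intervals of outcomes.

    ``outcomes`` is the per-patient frame produced by
    :func:`strokeburden.accounting.accumulate_all`.
    """
    if len(outcomes) == 0:
        raise DomainError("cannot summarize an empty outcome collection")
    total = outcomes["total"].to_numpy()
    qalys = outcomes["qalys"].to_numpy()
    lo_c, hi_c = np.percentile(total, [2.5, 97.5])
    lo_q, hi_q = np.percentile(qalys, [2.5, 97.5])
    return BurdenSummary(
        horizon=horizon,
        n=len(outcomes),
        total_cost=float(total.sum()),
        total_qalys=float(qalys.sum()),
        per_case_cost_mean=float(total.mean()),
        per_case_cost_ci=(float(lo_c), float(hi_c)),
        per_case_qaly_mean=float(qalys.mean()),
        per_case_qaly_ci=(float(lo_q), float(hi_q)),
        component_means=CostTriple(
            float(outcomes["medical"].mean()),
            float(outcomes["nonmedical"].mean()),
            float(outcomes["indirect"].mean()),
        ),
        per_case_lys_mean=float(outcomes["lys"].mean()),
    )


def to_usd(aud: float, usd_per_aud: float = 0.784) -> float:
    """Convert 2018 AUD to 2018 USD at the published exchange rate."""
    if not np.isfinite(aud):
        raise DomainError(f"amount must be finite, got {aud}")
    return aud * usd_per_aud
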