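"""On-chip lipid composition arithmetic and on/off-chip agreement checks.

Two lipid-in-octanol stock phases meet at a Y junction upstream of the
vesicle-formation junction; under laminar co-flow with matched viscosities
the mixed phase composition follows the relative flow rates, x_i = q_i with
q_i = Q_i / (Q_A + Q_B).  The relative flow rates can equally be read off
the relative stream cross-sections under the microscope (equal mean
velocity assumption).  Agreement between the binding constants of vesicles
produced on-chip and the off-chip exponential charge law validates that
mixed-phase compositions carry through to the bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import ChargeLaw

__all__ = [
    "CompositionPlan",
    "mixed_composition",
    "flows_from_cross_section",
    "compare_onchip_offchip",
]


@dataclass(frozen=True)
class CompositionPlan:
    """Flow rates of two lipid-octanol phases and their lipid compositions.

    ``lipid_a`` / ``lipid_b`` map lipid names to mole fractions (each summing
    to 1).  Flow rates are in any consistent unit; only ratios matter.
    """

    q_flow_a: float
    q_flow_b: float
    lipid_a: dict[str, float] = field(default_factory=dict)
    lipid_b: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.q_flow_a < 0 or self.q_flow_b < 0:
            raise ValueError("flow rates must be non-negative")
        if self.q_flow_a + self.q_flow_b == 0:
            raise ValueError("total flow rate must be positive")
        for name, comp in (("lipid_a", self.lipid_a), ("lipid_b", self.lipid_b)):
            if comp and not np.isclose(sum(comp.values()), 1.0):
                raise ValueError(f"{name} mole fractions must sum to 1")

    @property
    def q_total(self) -> float:
        return self.q_flow_a + self.q_flow_b

    @property
    def rel_a(self) -> float:
        """Relative flow rate q_A = Q_A / Q (= phase fraction x_A)."""
        return self.q_flow_a / self.q_total

    @property
    def rel_b(self) -> float:
        return self.q_flow_b / self.q_total


def mixed_composition(plan: CompositionPlan) -> dict[str, float]:
    """Per-lipid mole fractions of the mixed phase: the q-weighted average.

    fraction(L) = q_A * lipid_a[L] + q_B * lipid_b[L].  A convex
    combination, so every output fraction is bounded by the corresponding
    input fractions and the outputs sum to 1.
    """
    lipids = sorted(set(plan.lipid_a) | set(plan.lipid_b))
    if not lipids:
        raise ValueError("no lipid compositions given")
    return {
        lip: plan.rel_a * plan.lipid_a.get(lip, 0.0) + plan.rel_b * plan.lipid_b.get(lip, 0.0)
        for lip in lipids
    }


def flows_from_cross_section(width_a_px: float, width_b_px: float) -> tuple[float, float]:
    """Relative flow rates from the phases' stream widths at the junction.

    Under the equal-mean-velocity laminar assumption q_i is the stream's
    share of the total cross-section: q_i = w_i / (w_A + w_B).
    """
    if width_a_px < 0 or width_b_px < 0:
        raise ValueError("stream widths must be non-negative")
    total = width_a_px + width_b_px
    if total == 0:
        raise ValueError("both stream widths are zero")
    return width_a_px / total, width_b_px / total


def compare_onchip_offchip(
    onchip: pd.DataFrame,
    offchip_law: ChargeLaw,
    *,
    n_pg_col: str = "n_PG",
    kb_col: str = "k_b",
    z_threshold: float = 2.0,
) -> dict:
    """Standardised agreement of on-chip binding constants with the off-chip law.

    For each on-chip composition group, the mean K_B is compared with the
    off-chip exponential charge-law prediction via the standardised residual
    z = (mean - predicted) / sqrt(SE(mean)^2 + SE(prediction)^2); the
    prediction SE (delta method from the law-fit covariance) is included
    when the law carries one, since the off-chip law is itself estimated.
    The report carries per-group z scores, the maximum |z| and a pass flag
    (all |z| <= ``z_threshold``).

    Raises on fewer than 2 compositions or on any single-vesicle group
    (the SE of the mean is undefined).
    """
    if onchip.empty:
        raise ValueError("on-chip table is empty")
    groups = onchip.groupby(n_pg_col)[kb_col]
    if groups.ngroups < 2:
        raise ValueError("need >= 2 on-chip compositions")
    rows = []
    for n_pg, vals in groups:
        vals = vals.dropna()
        if len(vals) < 2:
            raise ValueError(f"composition n_PG={n_pg}: need >= 2 vesicles for a SE")
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        pred = float(offchip_law.predict(n_pg))
        se_pred = float(offchip_law.predict_se(n_pg))
        denom = np.hypot(se, se_pred) if np.isfinite(se_pred) else se
        rows.append(
            {"n_PG": float(n_pg), "mean_k_b": mean, "se_mean": se,
             "predicted_k_b": pred, "se_predicted": se_pred,
             "z": (mean - pred) / denom, "n": int(len(vals))}
        )
    per_group = pd.DataFrame(rows)
    max_abs_z = float(per_group["z"].abs().max())
    return {
        "per_group": per_group,
        "max_abs_z": max_abs_z,
        "passed": bool(max_abs_z <= z_threshold),
        "z_threshold": z_threshold,
    }
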