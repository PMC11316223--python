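"""Non-imaging quantitative assays: AFM Hertz-model fitting and qPCR ddCt.

AFM
---
Cell stiffness is probed with a four-sided pyramidal tip; force--indentation
curves follow the pyramidal (Sneddon/Bilodeau form) Hertz contact law

    F(d) = tan(alpha) / (sqrt(2) (1 - nu^2)) * E * (d - d0)^2   for d > d0

with half-angle ``alpha``, Poisson ratio ``nu`` (0.5 for incompressible
cells), Young's modulus ``E`` in Pa and contact point ``d0``.  Forces are
handled in nN and indentations in um, so the Pa * um^2 product is converted
to nN with a factor 1e-3.  The contact point is fitted jointly with E rather
than assumed at zero, since on real curves it is unknown.

qPCR
----
Relative expression by the ddCt method: per sample dCt = Ct_target -
Ct_reference; per group ddCt = mean dCt(group) - mean dCt(control); fold
change = 2^(-ddCt).  The control group has fold 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core import ValidationError

#: Pa * um^2 expressed in nN
_PA_UM2_TO_NN = 1e-3


@dataclass(frozen=True)
class TipSpec:
    """Pyramidal AFM tip: half-angle (deg), spring constant (N/m), Poisson ratio."""

    half_angle_deg: float = 35.0
    spring_constant: float = 0.01
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.half_angle_deg < 90.0):
            raise ValidationError("tip half-angle must be in (0, 90) degrees")
        if not (self.spring_constant > 0):
            raise ValidationError("spring constant must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5 + 1e-9):
            raise ValidationError("Poisson ratio must be in [0, 0.5]")

    @property
    def hertz_coefficient(self) -> float:
        """tan(alpha) / (sqrt(2) (1 - nu^2)) — geometry factor of the contact law."""
        alpha = np.deg2rad(self.half_angle_deg)
        return float(np.tan(alpha) / (np.sqrt(2.0) * (1.0 - self.poisson_ratio**2)))


@dataclass(frozen=True)
class ForceCurve:
    """An indentation grid (um, non-decreasing) and measured force (nN)."""

    indentation_um: np.ndarray
    force_nN: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.indentation_um, dtype=float)
        f = np.asarray(self.force_nN, dtype=float)
        if d.ndim != 1 or d.shape != f.shape or d.size == 0:
            raise ValidationError("indentation and force must be equal-length 1D arrays")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(f))):
            raise ValidationError("force curve values must be finite")
        if np.any(np.diff(d) < 0):
            raise ValidationError("indentation grid must be non-decreasing")
        object.__setattr__(self, "indentation_um", d)
        object.__setattr__(self, "force_nN", f)


@dataclass(frozen=True)
class HertzFit:
    """Result of a pyramidal Hertz fit."""

    youngs_modulus_Pa: float
    contact_offset_um: float
    residual_rms_nN: float
    degenerate: bool = False


def hertz_force(
    indentation_um: np.ndarray,
    youngs_modulus_Pa: float,
    tip: TipSpec,
    contact_offset_um: float = 0.0,
) -> np.ndarray:
    """Evaluate the pyramidal Hertz law; zero force before contact."""
    d = np.clip(np.asarray(indentation_um, dtype=float) - contact_offset_um, 0.0, None)
    return _PA_UM2_TO_NN * tip.hertz_coefficient * youngs_modulus_Pa * d**2


def _profiled_modulus(curve: ForceCurve, tip: TipSpec, d0: float) -> tuple[float, float]:
    """Least-squares E (closed form, E linear in the model) and SSE at fixed d0."""
    g = _PA_UM2_TO_NN * tip.hertz_coefficient * np.clip(curve.indentation_um - d0, 0.0, None) ** 2
    denom = float(g @ g)
    if denom == 0.0:
        return 0.0, float(curve.force_nN @ curve.force_nN)
    e = max(float(g @ curve.force_nN) / denom, 0.0)
    r = curve.force_nN - e * g
    return e, float(r @ r)


def fit_hertz(curve: ForceCurve, tip: TipSpec, min_points_past_contact: int = 10) -> HertzFit:
    """Fit Young's modulus and contact point to a force--indentation curve.

    The modulus enters the model linearly, so for each candidate contact
    point the optimal E >= 0 is closed-form; the contact point is found by a
    coarse scan over the indentation grid followed by bounded refinement.
    """
    d, f = curve.indentation_um, curve.force_nN
    if np.allclose(f, 0.0):
        return HertzFit(0.0, float(d[0]), 0.0, degenerate=True)
    # candidate contact points: grid values with enough points past contact
    hi = d[-min(min_points_past_contact, d.size - 1) - 1] if d.size > min_points_past_contact else d[0]
    cand = np.unique(np.concatenate([d[d <= hi], [d[0]]]))
    if cand.size == 0:
        cand = np.array([d[0]])
    sse = np.array([_profiled_modulus(curve, tip, c)[1] for c in cand])
    best = int(np.argmin(sse))
    lo = cand[max(best - 1, 0)]
    hi_b = cand[min(best + 1, cand.size - 1)]
    if hi_b > lo:
        res = optimize.minimize_scalar(
            lambda c: _profiled_modulus(curve, tip, c)[1],
            bounds=(float(lo), float(hi_b)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        d0 = float(res.x)
        if _profiled_modulus(curve, tip, d0)[1] > sse[best]:
            d0 = float(cand[best])
    else:
        d0 = float(cand[best])
    e, best_sse = _profiled_modulus(curve, tip, d0)
    return HertzFit(
        youngs_modulus_Pa=e,
        contact_offset_um=d0,
        residual_rms_nN=float(np.sqrt(best_sse / d.size)),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# qPCR


def ddct_fold_change(
    cts: pd.DataFrame,
    control_group: str,
    reference_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Relative expression per (gene, group) by the ddCt method.

    ``cts`` is a long-format table with columns ``sample``, ``group``,
    ``gene``, ``ct``.  Returns one row per (gene, group) with columns
    ``dct_mean``, ``ddct`` and ``fold`` (= 2^-ddCt); the control group's
    fold is identically 1.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required <= set(cts.columns):
        raise ValidationError(f"Ct table must have columns {sorted(required)}")
    if control_group not in set(cts["group"]):
        raise ValidationError(f"control group {control_group!r} not present")
    ref = cts[cts["gene"] == reference_gene].set_index("sample")["ct"]
    targets = cts[cts["gene"] != reference_gene].copy()
    missing = set(targets["sample"]) - set(ref.index)
    if missing:
        raise ValidationError(
            f"reference gene {reference_gene!r} missing for samples: {sorted(missing)}"
        )
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[targets["sample"]].to_numpy()
    out = (
        targets.groupby(["gene", "group"], sort=True)["dct"]
        .mean()
        .rename("dct_mean")
        .reset_index()
    )
    ctrl = out[out["group"] == control_group].set_index("gene")["dct_mean"]
    out["ddct"] = out["dct_mean"] - ctrl.loc[out["gene"]].to_numpy()
    out.loc[out["group"] == control_group, "ddct"] = 0.0  # exact by definition
    out["fold"] = 2.0 ** (-out["ddct"])
    return out
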