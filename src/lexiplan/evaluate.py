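"""Plan-quality evaluation: DVHs, V/D metrics, conformity, normalization.

Conventions (documented, asserted at boundaries in the tests):

* OAR volume metrics V_xGy use a strict ``>`` threshold ("receiving more
  than x Gy").
* Target coverage V_95% / V_110% and the conformity index use an inclusive
  ``>=`` threshold ("receive >= 95% of the prescribed dose").
* The clinical acceptance thresholds are inclusive: V_95% >= 99.5 and
  V_110% <= 0.2 both pass exactly at the boundary.
* Volumes are voxel counts — no partial-volume interpolation; grid
  resolution is the accuracy parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beams import DoseDistribution, DoseInfluence, dose_from_fluence
from .optimize import FluencePlan
from .phantom import Phantom

__all__ = [
    "PlanMetrics",
    "v_above",
    "dvh",
    "conformity_index",
    "normalize_to_median",
    "acceptance_check",
    "evaluate_plan",
]


def _members(dose: DoseDistribution | np.ndarray, structure: np.ndarray) -> np.ndarray:
    arr = dose.dose if isinstance(dose, DoseDistribution) else np.asarray(dose, float)
    structure = np.asarray(structure, dtype=bool)
    if not structure.any():
        raise ValueError("structure is empty")
    return arr[structure]


def v_above(dose, structure, threshold_gy: float) -> float:
    """Percent of the structure's voxels with dose strictly above the
    threshold (OAR convention, 'receiving more than x Gy')."""
    d = _members(dose, structure)
    return 100.0 * float(np.mean(d > threshold_gy))


def v_at_least(dose, structure, threshold_gy: float) -> float:
    """Percent of the structure's voxels with dose >= threshold (coverage
    convention, 'receive >= x')."""
    d = _members(dose, structure)
    return 100.0 * float(np.mean(d >= threshold_gy))


def dvh(dose, structure, bin_width_gy: float = 0.1) -> pd.DataFrame:
    """Cumulative dose-volume histogram.

    Returns a DataFrame with columns ``dose_gy`` (left bin edges, starting
    at 0) and ``volume_pct`` (percent of the structure receiving at least
    that dose); monotone non-increasing from 100% at 0 Gy.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be > 0")
    d = _members(dose, structure)
    top = max(float(d.max()), bin_width_gy)
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    # volume receiving >= edge
    vol = 100.0 * np.array([np.mean(d >= e) for e in edges])
    vol[0] = 100.0
    return pd.DataFrame({"dose_gy": edges, "volume_pct": vol})


def conformity_index(dose, ptv, prescription_dose: float) -> float:
    """CI_95%: all grid voxels receiving >= 95% of the prescription, divided
    by the PTV voxel count."""
    ptv = np.asarray(ptv, dtype=bool)
    if not ptv.any():
        raise ValueError("PTV is empty")
    arr = dose.dose if isinstance(dose, DoseDistribution) else np.asarray(dose, float)
    n_hot = int(np.sum(arr >= 0.95 * prescription_dose))
    return n_hot / int(ptv.sum())


def normalize_to_median(plan: FluencePlan, influence: DoseInfluence,
                        ptv: np.ndarray, target_median_gy: float) -> FluencePlan:
    """Scale the fluence so the median PTV dose equals the target exactly.

    All other dose values scale by the same factor (linearity), so relative
    metrics are invariant when their thresholds are scaled alongside.
    """
    dose = dose_from_fluence(influence, plan.weights)
    med = float(np.median(_members(dose, ptv)))
    if med <= 0:
        raise ValueError("cannot normalize: median PTV dose is zero")
    return plan.scaled(target_median_gy / med)


@dataclass
class PlanMetrics:
    """Per-plan DVH statistics plus the plan-level coverage and conformity."""

    prescription_dose: float
    ptv_v95: float            # % PTV receiving >= 95% of D^p
    ptv_v110: float           # % PTV receiving >= 110% of D^p
    ptv_median: float         # Gy
    ptv_max: float            # Gy
    ci95: float
    per_structure: dict[str, dict[str, float]] = field(default_factory=dict)

    _ALIASES = {
        "sb_v45": ("small_bowel", "v45"),
        "sb_v15": ("small_bowel", "v15"),
        "sb_dmean": ("small_bowel", "dmean"),
        "bladder_dmean": ("bladder", "dmean"),
        "rectum_dmean": ("rectum", "dmean"),
        "sigmoid_dmean": ("sigmoid", "dmean"),
    }

    def get(self, metric_id: str) -> float:
        """Fetch a metric by id: plan-level name ('ptv_v95', 'ci95'), a
        shorthand ('sb_v45'), or 'structure/stat' (e.g. 'rectum/dmax')."""
        if hasattr(self, metric_id) and not metric_id.startswith("_"):
            return float(getattr(self, metric_id))
        if metric_id in self._ALIASES:
            s, k = self._ALIASES[metric_id]
            return float(self.per_structure[s][k])
        if "/" in metric_id:
            s, k = metric_id.split("/", 1)
            return float(self.per_structure[s][k])
        raise KeyError(f"unknown metric id {metric_id!r}")

    def to_series(self) -> pd.Series:
        flat = {
            "ptv_v95": self.ptv_v95, "ptv_v110": self.ptv_v110,
            "ptv_median": self.ptv_median, "ptv_max": self.ptv_max,
            "ci95": self.ci95,
        }
        for s, stats in self.per_structure.items():
            for k, v in stats.items():
                flat[f"{s}/{k}"] = v
        return pd.Series(flat)


def acceptance_check(metrics: PlanMetrics) -> tuple[bool, list[str]]:
    """Clinical plan acceptability: V_95% >= 99.5 and V_110% <= 0.2
    (inclusive at the boundary). Returns (pass, reasons for failure)."""
    reasons = []
    if not metrics.ptv_v95 >= 99.5:
        reasons.append(f"PTV V95 = {metrics.ptv_v95:.2f}% < 99.5%")
    if not metrics.ptv_v110 <= 0.2:
        reasons.append(f"PTV V110 = {metrics.ptv_v110:.2f}% > 0.2%")
    return (not reasons), reasons


def evaluate_plan(dose: DoseDistribution, phantom: Phantom,
                  prescription_dose: float) -> PlanMetrics:
    """Compute the full evaluation panel for one dose distribution.

    Small bowel gets V_45Gy, V_15Gy and D_mean; bladder, rectum and sigmoid
    (and colon when present) get D_mean; the PTV gets V_95%, V_110%, median
    and max; plus CI_95%. Pure function of its inputs.
    """
    required = ["ptv", "small_bowel", "bladder", "rectum", "sigmoid"]
    for name in required:
        if name not in phantom.structures:
            raise ValueError(f"required structure {name!r} missing from phantom")
        if not phantom.structures[name].any():
            raise ValueError(f"required structure {name!r} is empty")

    Dp = prescription_dose
    ptv = phantom.mask("ptv")
    per: dict[str, dict[str, float]] = {}
    for name in ["small_bowel", "bladder", "rectum", "sigmoid", "colon"]:
        if name not in phantom.structures or not phantom.structures[name].any():
            continue
        d = _members(dose, phantom.mask(name))
        stats = {"dmean": float(d.mean()), "dmax": float(d.max())}
        if name == "small_bowel":
            stats["v45"] = v_above(dose, phantom.mask(name), 45.0)
            stats["v15"] = v_above(dose, phantom.mask(name), 15.0)
        per[name] = stats

    d_ptv = _members(dose, ptv)
    return PlanMetrics(
        prescription_dose=Dp,
        ptv_v95=v_at_least(dose, ptv, 0.95 * Dp),
        ptv_v110=v_at_least(dose, ptv, 1.10 * Dp),
        ptv_median=float(np.median(d_ptv)),
        ptv_max=float(d_ptv.max()),
        ci95=conformity_index(dose, ptv, Dp),
        per_structure=per,
    )
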