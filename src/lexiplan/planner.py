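"""High-level Model/Results interface.

``FluencePlanner`` bundles a phantom, a beam configuration and a wish-list
into a planning problem; ``fit()`` runs the 2-phase epsilon-constraint
optimization (with the coverage safeguard) and returns a ``PlanResult``
carrying the fluence plan, the dose distribution, the optimization trace
and the evaluation metrics, with ``summary()`` and DVH plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .beams import BeamConfig, DoseDistribution, DoseInfluence, compute_dose_influence, dose_from_fluence
from .evaluate import PlanMetrics, acceptance_check, dvh, evaluate_plan, normalize_to_median
from .optimize import (FluencePlan, InfeasibleError, OptimizationTrace,
                       OptimizerSettings, SolverError, ensure_coverage,
                       solve_2pec)
from .phantom import Phantom
from .wishlist import WishList, default_wishlist

__all__ = ["FluencePlanner", "PlanResult"]


class FluencePlanner:
    """Planning problem: phantom + beams + wish-list.

    Parameters
    ----------
    phantom : Phantom
        Voxelized anatomy with the structures the wish-list references.
    wishlist : WishList, optional
        Defaults to the shipped cervix wish-list at D^p = 46 Gy.
    beams : BeamConfig, optional
        Defaults to 20 equi-angular coplanar beams, 5 mm beamlets.
    settings : OptimizerSettings, optional
    """

    def __init__(self, phantom: Phantom, wishlist: WishList | None = None,
                 beams: BeamConfig | None = None,
                 settings: OptimizerSettings | None = None):
        self.phantom = phantom
        self.wishlist = wishlist or default_wishlist()
        self.beams = beams or BeamConfig()
        self.settings = settings or OptimizerSettings()
        self._influence: DoseInfluence | None = None

    @property
    def influence(self) -> DoseInfluence:
        if self._influence is None:
            self._influence = compute_dose_influence(self.phantom, self.beams)
        return self._influence

    def fit(self, enforce_coverage: bool = True) -> "PlanResult":
        """Run the lexicographic optimization and evaluate the plan.

        If the staged solve fails to close on a feasible plan with the
        configured settings, one retry is made with conservative solver
        settings (all cap rows kept in the Lagrangian, larger iteration
        budgets) — slower but markedly more robust.
        """
        settings = self.settings
        try:
            plan, trace = solve_2pec(self.influence, self.phantom,
                                     self.wishlist, settings)
        except (InfeasibleError, SolverError):
            settings = self.robust_settings()
            plan, trace = solve_2pec(self.influence, self.phantom,
                                     self.wishlist, settings)
        if enforce_coverage:
            plan, trace = ensure_coverage(plan, self.influence, self.phantom,
                                          self.wishlist, settings, trace)
        return PlanResult(model=self, plan=plan, trace=trace)

    def robust_settings(self) -> OptimizerSettings:
        """Conservative variant of the configured solver settings."""
        return replace(self.settings, lazy_rows=False, al_max_outer=24,
                       inner_maxiter=120)


@dataclass
class PlanResult:
    """Optimized plan plus everything needed to judge it."""

    model: FluencePlanner
    plan: FluencePlan
    trace: OptimizationTrace
    _dose: DoseDistribution | None = field(default=None, repr=False)

    @property
    def dose(self) -> DoseDistribution:
        if self._dose is None:
            self._dose = dose_from_fluence(self.model.influence, self.plan.weights)
        return self._dose

    @property
    def metrics(self) -> PlanMetrics:
        return evaluate_plan(self.dose, self.model.phantom,
                             self.model.wishlist.prescription_dose)

    def normalized(self, target_median_gy: float | None = None) -> "PlanResult":
        """Copy of the result scaled to an exact median PTV dose."""
        target = target_median_gy or self.model.wishlist.prescription_dose
        plan = normalize_to_median(self.plan, self.model.influence,
                                   self.model.phantom.mask("ptv"), target)
        return PlanResult(model=self.model, plan=plan, trace=self.trace)

    def summary(self) -> str:
        wl = self.model.wishlist
        m = self.metrics
        ok, reasons = acceptance_check(m)
        lines = [
            "Lexicographic fluence plan",
            "=" * 60,
            f"beams: {self.model.beams.n_beams} equi-angular, "
            f"{self.model.influence.n_beamlets} beamlets, "
            f"D^p = {wl.prescription_dose:g} Gy",
            f"PTV: V95 = {m.ptv_v95:.2f}%  V110 = {m.ptv_v110:.3f}%  "
            f"median = {m.ptv_median:.2f} Gy  max = {m.ptv_max:.2f} Gy",
            f"CI95 = {m.ci95:.3f}   clinical acceptance: "
            + ("PASS" if ok else "FAIL (" + "; ".join(reasons) + ")"),
            "-" * 60,
            f"{'structure':<16}{'Dmean (Gy)':>12}{'Dmax (Gy)':>12}{'V45 (%)':>10}{'V15 (%)':>10}",
        ]
        for name, stats in m.per_structure.items():
            lines.append(
                f"{name:<16}{stats['dmean']:>12.2f}{stats['dmax']:>12.2f}"
                + (f"{stats['v45']:>10.2f}{stats['v15']:>10.2f}"
                   if "v45" in stats else f"{'':>10}{'':>10}"))
        lines.append("-" * 60)
        lines.append(f"{'stage':<30}{'phase':>6}{'attained':>12}{'bound':>12}")
        for r in self.trace.records:
            bound = f"{r.bound:.4g}" if r.bound is not None else "-"
            lines.append(f"{r.objective:<30}{r.phase:>6}{r.attained:>12.4g}{bound:>12}")
        return "\n".join(lines)

    def plot_dvh(self, structures: list[str] | None = None, ax=None):
        """Cumulative DVH plot for the main structures."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 5))
        names = structures or [
            n for n in ("ptv", "small_bowel", "bladder", "rectum", "sigmoid")
            if n in self.model.phantom.structures]
        for name in names:
            curve = dvh(self.dose, self.model.phantom.mask(name))
            ax.plot(curve["dose_gy"], curve["volume_pct"], label=name)
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("volume (%)")
        ax.set_ylim(0, 105)
        ax.legend()
        ax.set_title("Cumulative DVH")
        return ax
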