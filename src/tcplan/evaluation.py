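"""Plan metrics, isoeffective plan comparison and cohort aggregation.

Evaluates every plan with DVH-based metrics (V_x, D_mean), expected
generalised EUD for the rectum and bladder, integral dose over the body,
and ``<TCP>``; compares the margin-based uniform plan (Plan A) with the
biologically optimised plan (Plan B) after both are linearly scaled to
the same expected tumour control (``<TCP> = 0.95``), and aggregates the
cohort with paired t-tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .biomaps import ClonogenMap, build_cell_map, scale_cohort
from .dose import BeamGeometry, EngineParams, FluencePlan, build_influence, compute_dose
from .grids import StructureSet, VoxelGrid
from .phantom import SyntheticPatient
from .radiobiology import (
    AlphaDistribution,
    EUDParams,
    ExpectationEngine,
    RadiobioParams,
)
from .uncertainty import ErrorModel
from .planning import (
    DEFAULT_OAR_OBJECTIVES,
    DEFAULT_UNIFORM_OBJECTIVES,
    OptimizerSettings,
    optimize_biological,
    optimize_uniform,
    scale_to_isoeffect,
)
from .uncertainty import expand_ctv

__all__ = [
    "PlanReport",
    "CohortComparison",
    "StudyResult",
    "dvh",
    "vx_pct",
    "integral_dose",
    "evaluate_plan",
    "compare_cohort",
    "run_study",
    "REPORT_METRICS",
]

#: metrics reported per plan, in presentation order
REPORT_METRICS = (
    "tcp_unscaled",
    "ctv_dmean_gy",
    "ptv_dmean_gy",
    "rectum_v60_pct",
    "rectum_v50_pct",
    "bladder_v65_pct",
    "rectum_eud_gy",
    "bladder_eud_gy",
    "hof_left_dmean_gy",
    "hof_right_dmean_gy",
    "integral_dose_gy_cc",
)


def dvh(
    total_dose: np.ndarray, structure_mask: np.ndarray, bin_gy: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram of a structure.

    Returns ``(dose_axis, volume_pct)`` where ``volume_pct[k]`` is the
    percentage of structure voxels with dose >= ``dose_axis[k]``, on a
    regular ``bin_gy`` grid from 0 to just above the structure maximum.
    The curve is non-increasing with ``V(0) = 100``.
    """
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot compute a DVH of an empty structure")
    doses = np.asarray(total_dose, dtype=float)[mask]
    top = max(float(doses.max()), 0.0) + bin_gy
    axis = np.arange(0.0, top + bin_gy, bin_gy)
    volume = 100.0 * np.mean(doses[None, :] >= axis[:, None], axis=1)
    return axis, volume


def vx_pct(total_dose: np.ndarray, structure_mask: np.ndarray, x_gy: float) -> float:
    """V_x: percentage of the structure receiving at least ``x_gy`` Gy."""
    mask = np.asarray(structure_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty structure")
    return 100.0 * float(np.mean(np.asarray(total_dose)[mask] >= x_gy))


def integral_dose(total_dose: np.ndarray, external_mask: np.ndarray, grid: VoxelGrid) -> float:
    """Integral dose over the body: sum of dose x voxel volume, in Gy cm^3."""
    mask = np.asarray(external_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty external mask")
    return float(np.asarray(total_dose)[mask].sum() * grid.voxel_volume / 1000.0)


@dataclass
class PlanReport:
    """All reported dose metrics of one (scaled) plan for one patient."""

    patient_id: str
    plan_name: str
    scale_factor: float
    expected_tcp: float
    metrics: dict[str, float]
    dvhs: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "plan_name": self.plan_name,
            "scale_factor": self.scale_factor,
            "expected_tcp": self.expected_tcp,
            "metrics": self.metrics,
            "flags": self.flags,
        }


def evaluate_plan(
    plan: FluencePlan,
    structures: StructureSet,
    clonogen_map: ClonogenMap,
    alpha_dist: AlphaDistribution,
    error_model: ErrorModel,
    params: RadiobioParams,
    patient_id: str = "patient",
    plan_name: str = "plan",
    tcp_unscaled: float | None = None,
    eud_params: EUDParams = EUDParams(6.0),
    n_shift_nodes: int = 5,
    with_dvh: bool = True,
) -> PlanReport:
    """Compute the full metric set for a plan.

    DV metrics and mean doses use the physical (unblurred) dose; rectum
    and bladder EUD and the TCP use the geometric-uncertainty expectation.
    """
    grid = plan.influence.grid
    _, D = compute_dose(plan)
    ctv = structures["ctv"]
    engine = ExpectationEngine(grid, ctv, error_model, n_shift_nodes)
    sampled = engine.sample_shifted(engine.blur(D / params.n_fractions))
    etcp = engine.expected_tcp_from_sampled(
        clonogen_map.rho[ctv], sampled, alpha_dist, params
    )
    metrics = {
        "ctv_dmean_gy": float(D[ctv].mean()),
        "rectum_v60_pct": vx_pct(D, structures["rectum"], 60.0),
        "rectum_v50_pct": vx_pct(D, structures["rectum"], 50.0),
        "bladder_v65_pct": vx_pct(D, structures["bladder"], 65.0),
        "hof_left_dmean_gy": float(D[structures["hof_left"]].mean()),
        "hof_right_dmean_gy": float(D[structures["hof_right"]].mean()),
        "integral_dose_gy_cc": integral_dose(D, structures["external"], grid),
    }
    if "ptv" in structures:
        metrics["ptv_dmean_gy"] = float(D[structures["ptv"]].mean())
    for organ in ("rectum", "bladder"):
        organ_engine = ExpectationEngine(grid, structures[organ], error_model, n_shift_nodes)
        metrics[f"{organ}_eud_gy"] = organ_engine.expected_eud(D, eud_params.a)
    if tcp_unscaled is not None:
        metrics["tcp_unscaled"] = float(tcp_unscaled)
    dvhs = {}
    if with_dvh:
        for name in ("ctv", "rectum", "bladder"):
            dvhs[name] = dvh(D, structures[name])
    return PlanReport(
        patient_id=patient_id,
        plan_name=plan_name,
        scale_factor=float(plan.meta.get("scale_factor", 1.0)),
        expected_tcp=float(etcp),
        metrics=metrics,
        dvhs=dvhs,
        flags=dict(plan.meta.get("requirements", {})),
    )


@dataclass
class CohortComparison:
    """Per-metric cohort summary of paired Plan A / Plan B values.

    ``mean_abs_change`` is the arithmetic mean of ``B - A``;
    ``mean_pct_change`` the mean of the per-patient percentage changes
    ``100 (B - A)/A`` (patients with ``A = 0`` excluded with a warning);
    ``p_value`` a two-sided paired t-test (NaN when degenerate).
    """

    table: pd.DataFrame

    def metric(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def compare_cohort(
    reports: list[tuple[PlanReport, PlanReport]],
    metrics: tuple[str, ...] | None = None,
) -> CohortComparison:
    """Aggregate paired plan reports across the cohort.

    Expects one ``(Plan A report, Plan B report)`` pair per patient with
    matching patient ids.  Needs >= 2 patients for t-tests (p is NaN for a
    single patient).
    """
    if not reports:
        raise ValueError("no reports to compare")
    for ra, rb in reports:
        if ra.patient_id != rb.patient_id:
            raise ValueError(
                f"mismatched patient pair: {ra.patient_id!r} vs {rb.patient_id!r}"
            )
    if metrics is None:
        metrics = tuple(
            m for m in REPORT_METRICS if all(
                m in ra.metrics and m in rb.metrics for ra, rb in reports
            )
        )
    rows = []
    for m in metrics:
        a = np.array([ra.metrics[m] for ra, _ in reports])
        b = np.array([rb.metrics[m] for _, rb in reports])
        diff = b - a
        nonzero = a != 0
        if not np.all(nonzero):
            warnings.warn(
                f"metric {m!r}: {int(np.sum(~nonzero))} patient(s) with A = 0 "
                "excluded from the % change mean",
                stacklevel=2,
            )
        pct = 100.0 * diff[nonzero] / a[nonzero]
        if len(reports) >= 2:
            if np.allclose(diff, 0.0):
                warnings.warn(f"metric {m!r}: A = B for all patients; p set to NaN", stacklevel=2)
                p = float("nan")
            else:
                p = float(stats.ttest_rel(b, a).pvalue)
        else:
            p = float("nan")
        rows.append({
            "metric": m,
            **{f"A_{ra.patient_id}": va for (ra, _), va in zip(reports, a)},
            **{f"B_{rb.patient_id}": vb for (_, rb), vb in zip(reports, b)},
            "mean_abs_change": float(diff.mean()),
            "mean_pct_change": float(pct.mean()) if pct.size else float("nan"),
            "p_value": p,
        })
    table = pd.DataFrame(rows).set_index("metric")
    return CohortComparison(table)


@dataclass
class StudyResult:
    """Everything the end-to-end planning study produces."""

    reports: list[tuple[PlanReport, PlanReport]]
    comparison: CohortComparison
    clonogen_maps: list[ClonogenMap]
    cohort_scale_factor: float
    failures: dict[str, str]

    @property
    def complete(self) -> bool:
        return not self.failures


def run_study(
    cohort: list[SyntheticPatient],
    error_model: ErrorModel,
    alpha_dist: AlphaDistribution,
    params: RadiobioParams = RadiobioParams(),
    beam_geometry: BeamGeometry = BeamGeometry(),
    engine_params: EngineParams = EngineParams(),
    uniform_specs=DEFAULT_UNIFORM_OBJECTIVES,
    oar_specs=DEFAULT_OAR_OBJECTIVES,
    settings: OptimizerSettings = OptimizerSettings(),
    target_tcp: float = 0.95,
    out_dir: str | Path | None = None,
    with_plots: bool = False,
) -> StudyResult:
    """End-to-end study: maps -> Plans A and B -> isoeffect -> comparison.

    All patients share one surrogate anatomy (the cohort generator builds
    identical organs), so the dose-influence matrix and the margin-based
    Plan A — which depends only on geometry — are computed once and
    shared; the patient-specific clonogen maps drive Plan B and every
    ``<TCP>`` evaluation.  Per-patient failures are recorded and the study
    continues; the result flags incompleteness.
    """
    if not cohort:
        raise ValueError("empty cohort")
    grid = cohort[0].grid
    base_structs = cohort[0].structures
    for k, pt in enumerate(cohort[1:], start=2):
        if pt.grid != grid or any(
            not np.array_equal(pt.structures[n], base_structs[n])
            for n in base_structs.names
        ):
            raise ValueError(
                f"patient {k} has different anatomy; the study assumes one "
                "shared surrogate anatomy across the cohort"
            )
    ptv = expand_ctv(
        base_structs["ctv"], error_model.margins_xyz, grid, base_structs["external"]
    )
    structures = base_structs.with_mask("ptv", ptv)

    # clonogen maps (threshold + cell map per patient, one cohort scale)
    cell_maps, thresholds = [], []
    for pt in cohort:
        cm, thr = build_cell_map(
            pt.probability_map, pt.density_area_map, pt.truth_tumour_mask,
            pt.structures["ctv"],
        )
        cell_maps.append(cm)
        thresholds.append(thr)
    clonogen_maps, cohort_scale = scale_cohort(cell_maps, grid, thresholds)

    influence = build_influence(grid, structures, beam_geometry, engine_params)
    plan_a = optimize_uniform(
        influence, structures, params, specs=uniform_specs, settings=settings
    )

    reports: list[tuple[PlanReport, PlanReport]] = []
    failures: dict[str, str] = {}
    for i, (pt, cmap) in enumerate(zip(cohort, clonogen_maps)):
        pid = f"patient_{i + 1}"
        try:
            plan_b = optimize_biological(
                influence, structures, cmap.rho, alpha_dist, error_model, params,
                oar_specs=oar_specs, settings=settings,
            )
            tcp_a = _plan_etcp(plan_a, cmap, alpha_dist, error_model, params,
                               structures, settings.n_shift_nodes)
            tcp_b = plan_b.meta["expected_tcp"]
            a95, s_a = scale_to_isoeffect(
                plan_a, cmap.rho, alpha_dist, error_model, params,
                structures["ctv"], target_tcp, n_shift_nodes=settings.n_shift_nodes,
            )
            b95, s_b = scale_to_isoeffect(
                plan_b, cmap.rho, alpha_dist, error_model, params,
                structures["ctv"], target_tcp, n_shift_nodes=settings.n_shift_nodes,
            )
            rep_a = evaluate_plan(a95, structures, cmap, alpha_dist, error_model,
                                  params, pid, "A", tcp_unscaled=tcp_a,
                                  n_shift_nodes=settings.n_shift_nodes)
            rep_b = evaluate_plan(b95, structures, cmap, alpha_dist, error_model,
                                  params, pid, "B", tcp_unscaled=tcp_b,
                                  n_shift_nodes=settings.n_shift_nodes)
            rep_b.flags.update({k: plan_b.meta[k] for k in
                                ("ctv_expected_v100_pct", "coverage_pass")})
            reports.append((rep_a, rep_b))
        except Exception as exc:  # noqa: BLE001 — study continues, failure logged
            warnings.warn(f"{pid} failed: {exc}", stacklevel=2)
            failures[pid] = str(exc)
    if not reports:
        raise RuntimeError(f"every patient failed: {failures}")
    comparison = compare_cohort(reports)
    result = StudyResult(reports, comparison, clonogen_maps, cohort_scale, failures)
    if out_dir is not None:
        _write_study(result, Path(out_dir), with_plots)
    return result


def _plan_etcp(plan, cmap, alpha_dist, error_model, params, structures, n_nodes):
    grid = plan.influence.grid
    ctv = structures["ctv"]
    engine = ExpectationEngine(grid, ctv, error_model, n_nodes)
    d, _ = compute_dose(plan)
    sampled = engine.sample_shifted(engine.blur(d))
    return engine.expected_tcp_from_sampled(cmap.rho[ctv], sampled, alpha_dist, params)


def _write_study(result: StudyResult, out_dir: Path, with_plots: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(out_dir / "cohort_comparison.csv")
    payload = {
        "cohort_scale_factor": result.cohort_scale_factor,
        "clonogen_totals": [m.total_cells for m in result.clonogen_maps],
        "thresholds": [m.threshold for m in result.clonogen_maps],
        "failures": result.failures,
        "reports": [
            {"A": ra.to_dict(), "B": rb.to_dict()} for ra, rb in result.reports
        ],
    }
    (out_dir / "study_report.json").write_text(json.dumps(payload, indent=2))
    if with_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for ra, rb in result.reports:
            fig, ax = plt.subplots(figsize=(6, 4))
            for rep, ls in ((ra, "-"), (rb, "--")):
                for name, (axis, vol) in rep.dvhs.items():
                    ax.plot(axis, vol, ls, label=f"{name} ({rep.plan_name})")
            ax.set_xlabel("Dose (Gy)")
            ax.set_ylabel("Volume (%)")
            ax.set_title(f"{ra.patient_id}: isoeffective Plans A vs B")
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(out_dir / f"dvh_{ra.patient_id}.png", dpi=120)
            plt.close(fig)
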