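"""End-to-end study driver.

Executes the full protocol for every simulated subject -- localizer run,
online ROI delineation, seven neurofeedback runs (true feedback for the
NF group, yoked sham for controls), pre/post Go/No-go testing -- then
all offline and group-level analyses, deterministically from one master
seed. Per-subject sub-seeds are spawned by key, so adding a subject
never perturbs existing ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nfloop.config import StudyConfig, validate_config
from nfloop.gonogo import HANDS, SESSIONS, mean_go_rt, simulate_gonogo
from nfloop.offline import event_related_average, fit_first_level, preprocess_offline, roi_betas
from nfloop.paradigm import make_localizer_design, make_nf_design, design_to_regressor
from nfloop.phantom import ANALYSIS_ROIS, build_phantom
from nfloop.realtime import (
    OnlineGlm,
    OnlinePreprocessor,
    RoiSet,
    assign_yoked_sources,
    delineate_sma,
    run_nf_loop,
)
from nfloop.simulate import SubjectState, learning_trajectory, simulate_run
from nfloop import stats as gstats
from nfloop import wholebrain as wb

logger = logging.getLogger(__name__)


class StudyError(RuntimeError):
    """A pipeline stage failed; message carries the stage tag."""


def _subject_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    roi_voxels: int
    betas: pd.DataFrame  # run x roi long table
    mean_beta_map: np.ndarray
    run_beta_maps: np.ndarray  # (n_runs, *dims)
    residual_sample: np.ndarray  # one residual volume stack for smoothness
    feedback_traces: list[pd.DataFrame]
    gonogo: pd.DataFrame
    event_avg_first: object
    event_avg_last: object


@dataclass
class StudyReport:
    config: StudyConfig
    roi_table: pd.DataFrame
    beta_table: pd.DataFrame
    sma_anova: gstats.AnovaResult
    trend_interaction: dict
    paired_first_last: dict
    run_regressions: dict
    slope_comparison: dict
    roi_regressions: pd.DataFrame
    deviation_contrast: pd.DataFrame
    gonogo: dict
    nf_performance: gstats.RegressionResult
    mc_threshold: wb.McThreshold
    cluster_tables: dict
    event_averages: dict
    beta_by_run: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.roi_table.to_csv(out / "roi_table.tsv", sep="\t", index=False)
        self.beta_table.to_csv(out / "beta_table.tsv", sep="\t", index=False)
        self.sma_anova.table.to_csv(out / "sma_anova.tsv", sep="\t", index=False)
        self.beta_by_run.to_csv(out / "beta_by_run.tsv", sep="\t", index=False)
        self.deviation_contrast.to_csv(out / "deviation_contrast.tsv", sep="\t", index=False)
        self.roi_regressions.to_csv(out / "roi_regressions.tsv", sep="\t", index=False)
        self.gonogo["anova"].table.to_csv(out / "gonogo_anova.tsv", sep="\t", index=False)
        self.gonogo["posthoc"].to_csv(out / "gonogo_posthoc.tsv", sep="\t", index=False)
        for name, tab in self.cluster_tables.items():
            tab.to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
        for name, ev in self.event_averages.items():
            ev.to_frame().to_csv(out / f"event_average_{name}.tsv", sep="\t", index=False)
        (out / "summary.txt").write_text(self.summary())

    def summary(self) -> str:
        lines = ["Neurofeedback study report", "=" * 30]
        lines.append(
            f"subjects: {self.config.n_per_group}+{self.config.n_per_group}, "
            f"runs: {self.config.n_runs}, TR {self.config.tr} s"
        )
        g = self.sma_anova.effect("group")
        lines.append(f"SMA group effect: F({g.df1:.0f},{g.df2:.0f}) = {g.F:.2f}, p = {g.p:.4g}")
        ti = self.trend_interaction
        lines.append(
            f"group x run linear trend: F({ti['df1']},{ti['df2']}) = {ti['F']:.2f}, p = {ti['p']:.4g}"
        )
        for grp, reg in self.run_regressions.items():
            lines.append(
                f"{grp} run regression: y = {reg.slope:.3f}x + {reg.intercept:.3f}, "
                f"F({reg.df1},{reg.df2}) = {reg.F:.2f}, r2 = {reg.r2:.2f}, p = {reg.p:.4g}"
            )
        sc = self.slope_comparison
        lines.append(f"slope difference: t({sc['df']}) = {sc['t']:.2f}, p = {sc['p']:.4g}")
        lines.append(
            f"cluster threshold: {self.mc_threshold.min_cluster_voxels} voxels "
            f"({self.mc_threshold.min_cluster_mm3:.0f} mm3) at voxel p "
            f"{self.mc_threshold.voxel_p}, alpha {self.mc_threshold.alpha}"
        )
        for name, tab in self.cluster_tables.items():
            lines.append(f"clusters [{name}]: {len(tab)}")
        return "\n".join(lines) + "\n"


def _simulate_subject(
    config: StudyConfig, index: int, group: str
) -> tuple[SubjectState, object]:
    seed = _subject_seed(config.master_seed, index)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
    if group == "NF":
        base, slope = config.nf_base_amp, config.nf_slope
    else:
        base, slope = config.control_base_amp, config.control_slope
    base = max(0.0, base + rng.normal(0.0, config.amp_between_sd))
    sma_traj = learning_trajectory(group, config.n_runs, base, slope)
    run_amps = {"SMA": sma_traj}
    for region in ANALYSIS_ROIS:
        if region == "SMA":
            continue
        amp = max(0.0, config.nonspecific_amp + rng.normal(0.0, config.amp_between_sd))
        run_amps[region] = np.full(config.n_runs, amp)
    state = SubjectState(
        group=group,
        subject_id=f"{'nf' if group == 'NF' else 'ct'}{index:02d}",
        seed=seed,
        run_amplitudes=run_amps,
        localizer_amplitudes={r: config.localizer_amp for r in ANALYSIS_ROIS},
        ar1_phi=config.ar1_phi,
        sigma=config.sigma,
        baseline=config.baseline,
        drift_slope=config.drift_slope,
    )
    phantom = build_phantom(config.dims, config.voxel_size_mm, seed=seed)
    return state, phantom


def _localize(config: StudyConfig, state: SubjectState, phantom) -> RoiSet:
    design = make_localizer_design(config.tr)
    rec = simulate_run(phantom, state, design, run_index=0)
    pre = OnlinePreprocessor(config.online_fwhm_mm, config.voxel_size_mm)
    glm = OnlineGlm(n_predictors=2)
    reg = design_to_regressor(design, "tapping")
    for i in range(design.n_volumes):
        vol = pre.process(rec.volumes[i])
        glm.update(vol, np.array([reg[i], 1.0]))
    t_map = glm.t_map(0)
    if t_map is None:
        raise StudyError(f"[localizer] GLM rank-deficient for {state.subject_id}")
    sma = delineate_sma(t_map, phantom.sma_bbox, config.localizer_threshold)
    return RoiSet(sma_mask=sma, reference_mask=phantom.masks["REF_SLAB"])


def _analyze_runs(
    config: StudyConfig, state: SubjectState, phantom, rois: RoiSet, traces: list[pd.DataFrame]
) -> SubjectResult:
    design = make_nf_design(config.tr)
    masks = {r: phantom.masks[r] for r in ANALYSIS_ROIS}
    masks["SMA"] = rois.sma_mask  # the localizer-defined target drives the analysis
    beta_rows = []
    run_maps = []
    residual_sample = None
    ev_first = ev_last = None
    for run in range(1, config.n_runs + 1):
        rec = simulate_run(phantom, state, design, run_index=run)
        pp = preprocess_offline(
            rec,
            hp_cycles=config.hp_cycles,
            fwhm_mm=config.offline_fwhm_mm,
            voxel_size_mm=config.voxel_size_mm,
        )
        fit = fit_first_level(pp, compute_residuals=(run == config.n_runs))
        run_maps.append(fit.task_beta_map)
        if run == config.n_runs:
            residual_sample = fit.residuals[::40].copy()
        betas = roi_betas(pp, masks)
        for roi_name, b in betas.items():
            beta_rows.append(
                {
                    "subject": state.subject_id,
                    "group": state.group,
                    "run": run,
                    "roi": roi_name,
                    "beta": b,
                }
            )
        if run == 1:
            ev_first = event_related_average(pp, rois.sma_mask)
        if run == config.n_runs:
            ev_last = event_related_average(pp, rois.sma_mask)
    run_maps = np.stack(run_maps)
    rng = np.random.default_rng(np.random.SeedSequence(state.seed, spawn_key=(4242,)))
    shift = (
        config.rt_post_shift_nf_right_ms
        if state.group == "NF"
        else config.rt_post_shift_other_ms
    )
    effect = {}
    for hand in HANDS:
        for session in SESSIONS:
            rt = config.rt_pre_ms
            if session == "post" and hand == "right":
                rt += shift
            elif session == "post":
                rt += config.rt_post_shift_other_ms
            effect[(hand, session)] = rt
    gng = simulate_gonogo(effect, seed=int(rng.integers(2**31)))
    return SubjectResult(
        subject_id=state.subject_id,
        group=state.group,
        roi_voxels=rois.n_sma,
        betas=pd.DataFrame(beta_rows),
        mean_beta_map=run_maps.mean(axis=0),
        run_beta_maps=run_maps,
        residual_sample=residual_sample,
        feedback_traces=traces,
        gonogo=gng,
        event_avg_first=ev_first,
        event_avg_last=ev_last,
    )


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full simulated study and all analyses, seeded end to end."""
    issues = validate_config(config)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise StudyError("[config] " + "; ".join(i.message for i in errors))
    for i in issues:
        logger.warning("[config] %s", i.message)

    nf_design = make_nf_design(config.tr)
    subjects: list[SubjectResult] = []
    nf_traces: dict[str, list[pd.DataFrame]] = {}

    # NF group first: their recorded traces form the sham pool
    nf_states = []
    for idx in range(config.n_per_group):
        state, phantom = _simulate_subject(config, idx, "NF")
        rois = _localize(config, state, phantom)
        traces = []
        for run in range(1, config.n_runs + 1):
            rec = simulate_run(phantom, state, nf_design, run_index=run)
            traces.append(
                run_nf_loop(
                    rec,
                    rois,
                    mode="true_feedback",
                    preprocessor=OnlinePreprocessor(config.online_fwhm_mm, config.voxel_size_mm),
                )
            )
        nf_traces[state.subject_id] = traces
        subjects.append(_analyze_runs(config, state, phantom, rois, traces))
        nf_states.append(state.subject_id)

    pool = nf_states[: config.n_yoked_sources]
    control_ids = [f"ct{config.n_per_group + idx:02d}" for idx in range(config.n_per_group)]
    yoke_seed = _subject_seed(config.master_seed, 10_000)
    yoking = assign_yoked_sources(pool, control_ids, seed=yoke_seed)

    for idx in range(config.n_per_group):
        state, phantom = _simulate_subject(config, config.n_per_group + idx, "control")
        rois = _localize(config, state, phantom)
        source = nf_traces[yoking[state.subject_id]]
        traces = []
        for run in range(1, config.n_runs + 1):
            rec = simulate_run(phantom, state, nf_design, run_index=run)
            traces.append(
                run_nf_loop(
                    rec,
                    rois,
                    mode="sham",
                    sham_source=source[run - 1],
                    preprocessor=OnlinePreprocessor(config.online_fwhm_mm, config.voxel_size_mm),
                )
            )
        subjects.append(_analyze_runs(config, state, phantom, rois, traces))

    return _group_analyses(config, subjects)


def _group_analyses(config: StudyConfig, subjects: list[SubjectResult]) -> StudyReport:
    beta_table = pd.concat([s.betas for s in subjects], ignore_index=True)
    roi_table = pd.DataFrame(
        {
            "subject": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "sma_voxels": [s.roi_voxels for s in subjects],
        }
    )
    sma = beta_table[beta_table.roi == "SMA"]
    sma_anova = gstats.mixed_anova(
        sma, dv="beta", within=["run"], between=["group"], subject="subject"
    )
    trend = gstats.linear_trend_interaction(sma)
    paired = {}
    regs = {}
    for grp in ("NF", "control"):
        g = sma[sma.group == grp]
        first = g[g.run == 1].sort_values("subject").beta.to_numpy()
        last = g[g.run == config.n_runs].sort_values("subject").beta.to_numpy()
        paired[grp] = gstats.paired_t(last, first)
        means = g.groupby("run").beta.mean().sort_index().to_numpy()
        regs[grp] = gstats.fit_run_regression(means)
    slope_cmp = gstats.compare_slopes(regs["NF"], regs["control"])

    roi_reg_rows = []
    for roi_name in ANALYSIS_ROIS:
        for grp in ("NF", "control"):
            g = beta_table[(beta_table.roi == roi_name) & (beta_table.group == grp)]
            means = g.groupby("run").beta.mean().sort_index().to_numpy()
            r = gstats.fit_run_regression(means)
            roi_reg_rows.append(
                {
                    "roi": roi_name,
                    "group": grp,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "F": r.F,
                    "p": r.p,
                    "r2": r.r2,
                }
            )
    roi_regressions = pd.DataFrame(roi_reg_rows)
    deviation = gstats.deviation_contrast_3way(beta_table)

    gng = gstats.analyze_gonogo(
        {s.subject_id: s.gonogo for s in subjects},
        {s.subject_id: s.group for s in subjects},
    )

    nf_subjects = [s for s in subjects if s.group == "NF"]
    delta_beta = []
    delta_rt = []
    for s in nf_subjects:
        b = s.betas[s.betas.roi == "SMA"].set_index("run").beta
        delta_beta.append(b.loc[config.n_runs] - b.loc[1])
        cells = mean_go_rt(s.gonogo).set_index(["hand", "session"]).rt_ms
        delta_rt.append(cells.loc[("right", "pre")] - cells.loc[("right", "post")])
    nf_perf = gstats.nf_performance_regression(np.array(delta_beta), np.array(delta_rt))

    # whole-brain maps
    groups = np.array([s.group for s in subjects])
    mean_maps = np.stack([s.mean_beta_map for s in subjects])
    nf_maps = mean_maps[groups == "NF"]
    ct_maps = mean_maps[groups == "control"]
    resid = np.concatenate([s.residual_sample for s in subjects[:4]])
    fwhm = wb.estimate_smoothness(resid, config.voxel_size_mm)
    mc = wb.monte_carlo_min_cluster(
        config.dims,
        fwhm,
        voxel_p=config.voxel_p,
        alpha=config.alpha,
        n_iter=config.mc_iterations,
        connectivity=config.connectivity,
        seed=_subject_seed(config.master_seed, 20_000),
        voxel_size_mm=config.voxel_size_mm,
    )
    cluster_tables = {}
    maps = {
        "nf_group": wb.rfx_one_sample(nf_maps, config.voxel_size_mm),
        "control_group": wb.rfx_one_sample(ct_maps, config.voxel_size_mm),
        "nf_gt_control": wb.rfx_two_sample(nf_maps, ct_maps, config.voxel_size_mm),
        "interaction": wb.voxelwise_interaction(
            np.stack([s.run_beta_maps for s in subjects]), groups, config.voxel_size_mm
        ),
    }
    for name, smap in maps.items():
        _, table = wb.apply_cluster_threshold(smap, config.voxel_p, mc)
        cluster_tables[name] = table

    beta_by_run = (
        beta_table[beta_table.roi == "SMA"]
        .groupby(["group", "run"], as_index=False)
        .beta.agg(["mean", "sem"])
        .reset_index()
    )
    event_averages = {
        "nf_first_run": nf_subjects[0].event_avg_first,
        "nf_last_run": nf_subjects[0].event_avg_last,
    }
    return StudyReport(
        config=config,
        roi_table=roi_table,
        beta_table=beta_table,
        sma_anova=sma_anova,
        trend_interaction=trend,
        paired_first_last=paired,
        run_regressions=regs,
        slope_comparison=slope_cmp,
        roi_regressions=roi_regressions,
        deviation_contrast=deviation,
        gonogo=gng,
        nf_performance=nf_perf,
        mc_threshold=mc,
        cluster_tables=cluster_tables,
        event_averages=event_averages,
        beta_by_run=beta_by_run,
    )
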