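"""Shared fixtures: small phantoms, subject states, and a replicate driver."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nfloop.offline import fit_first_level, preprocess_offline, roi_betas
from nfloop.paradigm import design_to_regressor, make_localizer_design, make_nf_design
from nfloop.phantom import ANALYSIS_ROIS, build_phantom
from nfloop.realtime import OnlineGlm, OnlinePreprocessor, RoiSet, delineate_sma
from nfloop.simulate import SubjectState, learning_trajectory, simulate_run
from nfloop import stats as gstats
from nfloop import wholebrain as wb

SMALL_DIMS = (16, 16, 10)


@pytest.fixture(scope="session")
def nf_design():
    return make_nf_design(2.0)


@pytest.fixture(scope="session")
def localizer_design():
    return make_localizer_design(2.0)


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom(SMALL_DIMS, seed=7)


def make_state(
    group: str = "NF",
    seed: int = 3,
    n_runs: int = 7,
    base_amp: float | None = None,
    slope: float | None = None,
    sigma: float = 1.0,
    ar1_phi: float = 0.3,
    drift_slope: float = 1.0,
    cosine_amps: tuple[float, ...] = (0.5, 0.3),
    nonspecific_amp: float = 0.3,
    **kw,
) -> SubjectState:
    amps = {"SMA": learning_trajectory(group, n_runs, base_amp, slope)}
    for r in ANALYSIS_ROIS:
        if r != "SMA":
            amps[r] = np.full(n_runs, nonspecific_amp)
    return SubjectState(
        group=group,
        subject_id=f"{group}-{seed}",
        seed=seed,
        run_amplitudes=amps,
        localizer_amplitudes={r: 1.0 for r in ANALYSIS_ROIS},
        sigma=sigma,
        ar1_phi=ar1_phi,
        drift_slope=drift_slope,
        cosine_amps=cosine_amps,
        **kw,
    )


@pytest.fixture
def state_factory():
    return make_state


def localize_subject(phantom, state, fwhm_mm: float = 8.0, threshold: float = 5.0):
    """Online localizer: stream, cumulative GLM, t-threshold delineation."""
    design = make_localizer_design(2.0)
    rec = simulate_run(phantom, state, design, run_index=0)
    pre = OnlinePreprocessor(fwhm_mm, phantom.voxel_size_mm)
    glm = OnlineGlm(2)
    reg = design_to_regressor(design, "tapping")
    for i in range(design.n_volumes):
        glm.update(pre.process(rec.volumes[i]), np.array([reg[i], 1.0]))
    sma = delineate_sma(glm.t_map(0), phantom.sma_bbox, threshold)
    return RoiSet(sma_mask=sma, reference_mask=phantom.masks["REF_SLAB"])


def run_replicate(seed: int, n_per_group: int = 10, n_runs: int = 7, mc_iter: int = 500) -> dict:
    """One full NF-vs-sham study replicate with SMA-only group coupling.

    Every subject goes through the localizer and online ROI delineation,
    seven simulated NF runs, offline preprocessing, ROI-GLM betas on the
    delineated target, and voxel-wise first-level fits; group analyses
    yield the per-group run regressions and the cluster-corrected
    two-sample map. (The thermometer replay itself does not influence
    the generated data, so the feedback loop is exercised elsewhere.)
    """
    design = make_nf_design(2.0)
    rows = []
    mean_maps = []
    groups = []
    sma_union = None
    resid = None
    for s in range(2 * n_per_group):
        group = "NF" if s < n_per_group else "control"
        sseed = int(np.random.SeedSequence(seed, spawn_key=(s,)).generate_state(1)[0] % 2**31)
        phantom = build_phantom(seed=sseed)
        state = make_state(group, seed=sseed, n_runs=n_runs)
        rois = localize_subject(phantom, state)
        sma_union = (
            phantom.masks["SMA"] if sma_union is None else (sma_union | phantom.masks["SMA"])
        )
        maps = []
        for run in range(1, n_runs + 1):
            rec = simulate_run(phantom, state, design, run_index=run)
            pp = preprocess_offline(rec)
            fit = fit_first_level(pp, compute_residuals=(run == n_runs and s == 0))
            if fit.residuals is not None:
                resid = fit.residuals[::40].copy()
            maps.append(fit.task_beta_map)
            beta = roi_betas(pp, {"SMA": rois.sma_mask})["SMA"]
            rows.append({"subject": s, "group": group, "run": run, "beta": beta})
        mean_maps.append(np.mean(maps, axis=0))
        groups.append(group)
    table = pd.DataFrame(rows)
    regs = {}
    for grp in ("NF", "control"):
        means = (
            table[table.group == grp].groupby("run").beta.mean().sort_index().to_numpy()
        )
        regs[grp] = gstats.fit_run_regression(means)
    mean_maps = np.stack(mean_maps)
    groups = np.array(groups)
    smap = wb.rfx_two_sample(mean_maps[groups == "NF"], mean_maps[groups == "control"])
    fwhm = wb.estimate_smoothness(resid)
    mc = wb.monte_carlo_min_cluster(
        smap.values.shape, fwhm, voxel_p=0.01, alpha=0.05, n_iter=mc_iter, seed=seed
    )
    thr, clusters = wb.apply_cluster_threshold(smap, 0.01, mc)
    overlap = bool(((thr.values > 0) & sma_union).any()) if len(clusters) else False
    return {
        "table": table,
        "nf_reg": regs["NF"],
        "control_reg": regs["control"],
        "clusters": clusters,
        "sma_cluster_overlap": overlap,
        "fwhm": fwhm,
    }
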