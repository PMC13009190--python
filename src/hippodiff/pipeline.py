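"""End-to-end orchestration: simulate -> geometry -> fit -> sample -> stats.

A :class:`RunConfig` (JSON-serializable) fully determines a run: every
stochastic stage derives its generator from the config seed, so reruns
are bit-identical and a resumed run (after deleting downstream outputs)
reproduces the same final results.  Each stage writes its outputs plus a
manifest (config hash, seed, package version) under the run directory;
on resume, a stage whose manifest matches the current config is loaded
instead of recomputed.

The default configuration is a reduced-scale profile (12 participants,
small grid, 200 spin permutations) that completes in minutes on one CPU;
``full_scale()`` gives the study-size profile (88 participants, 2500
permutations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import model_fitting as mf
from . import parcel_stats as ps
from . import synthetic_cohort as sc
from . import vertex_stats as vs
from .signal_models import AcquisitionScheme, default_scheme

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report", "full_scale"]

MICRO_METRICS = ("f_neurite", "f_soma", "f_extracellular", "Rsoma",
                 "MD", "FA")


@dataclass
class RunConfig:
    """Serializable description of a complete synthetic study run."""

    out_dir: str = "hippodiff_run"
    seed: int = 0
    # cohort
    n_participants: int = 12
    age_range: tuple = (8.0, 19.0)
    sex_ratio: float = 42.0 / 88.0
    age_distribution: str = "uniform"
    # domain / acquisition
    grid_shape: tuple = (20, 14, 10)
    curved: bool = True
    voxel_size: float = 1.0
    snr: float = 50.0
    noise_model: str = "rician"
    delta: float = 7.0
    Delta: float = 24.0
    # surface
    n_ap: int = 25
    n_pd: int = 15
    # fitting
    models: tuple = ("dti", "sandi", "noddi")
    sandi_starts: int = 3
    sandi_prescreen: int = 64
    sandi_prior: tuple = (0.01, 0.01, 0.015, 0.03, 0.01)
    noddi_starts: int = 5
    restrict_to_surface: bool = True
    # statistics
    n_perm: int = 200
    effect_spec: dict | None = None   # None -> default_effect_spec()

    def spec_effect(self) -> sc.EffectSpec:
        if self.effect_spec is None:
            return sc.default_effect_spec()
        eff = {p: {lab: sc.ParameterEffect(**e) for lab, e in per.items()}
               for p, per in self.effect_spec["effects"].items()}
        return sc.EffectSpec(effects=eff,
                             axis=self.effect_spec.get("axis", {})).validate()

    # -- (de)serialization -------------------------------------------------
    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=list)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {unknown}")
        for key in ("age_range", "grid_shape", "models", "sandi_prior"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def full_scale(**overrides) -> RunConfig:
    """Study-size profile: 88 participants, 2500 spin permutations."""
    cfg = RunConfig(n_participants=88, n_perm=2500, **overrides)
    return cfg


# --------------------------------------------------------------------------
# Stage plumbing
# --------------------------------------------------------------------------

def _manifest_path(out: Path, stage: str) -> Path:
    return out / stage / "manifest.json"


def _write_manifest(out: Path, stage: str, cfg: RunConfig, extra=None):
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    manifest = {"stage": stage, "config_hash": cfg.config_hash(),
                "seed": cfg.seed, "time": time.time()}
    if extra:
        manifest.update(extra)
    _manifest_path(out, stage).write_text(json.dumps(manifest, indent=2))


def _stage_cached(out: Path, stage: str, cfg: RunConfig) -> bool:
    p = _manifest_path(out, stage)
    if not p.exists():
        return False
    try:
        manifest = json.loads(p.read_text())
    except json.JSONDecodeError:
        return False
    return manifest.get("config_hash") == cfg.config_hash()


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute all stages in dependency order; returns in-memory results.

    Stages: cohort/domain simulation, Laplace geometry + surface, signal
    simulation + model fitting + surface sampling per participant and
    hemisphere, parcel statistics, vertex statistics.  Each stage writes
    a manifest; ``resume=True`` reuses stages whose manifest matches the
    config.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    # ---- stage: cohort + domain + scheme --------------------------------
    stage = "simulate"
    scheme = default_scheme(delta=config.delta, Delta=config.Delta)
    cohort_spec = sc.CohortSpec(
        n_participants=config.n_participants, age_range=config.age_range,
        sex_ratio=config.sex_ratio, seed=config.seed,
        age_distribution=config.age_distribution)
    if resume and _stage_cached(out, stage, config):
        logger.info("resume: reusing %s", stage)
        cohort = pd.read_csv(out / stage / "cohort.tsv", sep="\t")
        dom_npz = np.load(out / stage / "domain.npz")
        domain = geo.HippDomain(
            mask=dom_npz["mask"], voxel_size=config.voxel_size,
            true_coords={ax: dom_npz[f"true_{ax}"] for ax in ("AP", "PD",
                                                              "IO")})
    else:
        cohort = sc.generate_cohort(cohort_spec)
        domain = sc.generate_domain(
            grid_shape=config.grid_shape, seed=config.seed,
            curved=config.curved, voxel_size=config.voxel_size)
        sc.write_simulation(out / stage, cohort, domain, scheme,
                            {"config_hash": config.config_hash()})
        np.savez_compressed(
            out / stage / "domain.npz", mask=domain.mask,
            **{f"true_{ax}": domain.true_coords[ax] for ax in ("AP", "PD",
                                                               "IO")})
        _write_manifest(out, stage, config)
    logger.info("stage simulate done (%.1fs)", time.time() - t_start)

    # ---- stage: geometry -------------------------------------------------
    stage = "geometry"
    t0 = time.time()
    for axis in ("AP", "PD", "IO"):
        geo.solve_laplace(domain, axis)
    surface = geo.build_midthickness_surface(domain, n_ap=config.n_ap,
                                             n_pd=config.n_pd)
    grads = {ax: geo.gradient_field(domain.psi[ax], domain.mask,
                                    domain.voxel_size)
             for ax in ("AP", "PD", "IO")}
    (out / stage).mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / stage / "geometry.npz",
                        **{f"psi_{ax}": domain.psi[ax]
                           for ax in ("AP", "PD", "IO")},
                        vertices_native=surface.vertices_native,
                        vertices_unfolded=surface.vertices_unfolded,
                        faces=surface.faces, valid=surface.valid)
    geo.save_surface_gifti(surface, out / stage / "midthickness.surf.gii")
    _write_manifest(out, stage, config)
    logger.info("stage geometry done (%.1fs)", time.time() - t0)

    # macrostructure (identical across participants: one shared domain)
    thickness, gyrification, volume_table = geo.macrostructure(domain,
                                                               surface)
    volume_table.to_csv(out / stage / "subfield_volume.tsv", sep="\t",
                        index=False)

    # voxels that the surface actually samples (plus the full mask option)
    if config.restrict_to_surface:
        idx = np.floor(surface.vertices_native / config.voxel_size
                       ).astype(int)
        fit_mask = np.zeros(domain.mask.shape, dtype=bool)
        inb = np.all((idx >= 0) & (idx < np.array(domain.mask.shape)),
                     axis=1)
        fit_mask[tuple(idx[inb].T)] = True
        fit_mask &= domain.mask
    else:
        fit_mask = domain.mask

    # ---- stage: per-subject simulate + fit + sample ----------------------
    stage = "fit"
    t0 = time.time()
    effect_spec = config.spec_effect()
    subjects = cohort["participant"].unique()
    n_vert = surface.n_vertices
    vertex_maps = {m: np.full((len(subjects), 2, n_vert), np.nan)
                   for m in MICRO_METRICS}
    for m in ("long_axis", "tangential", "radial"):
        vertex_maps[m] = np.full((len(subjects), 2, n_vert), np.nan)
    rows = []
    if resume and _stage_cached(out, stage, config):
        logger.info("resume: reusing %s", stage)
        data = np.load(out / stage / "vertex_maps.npz")
        vertex_maps = {k: data[k] for k in data.files}
        table_long = pd.read_csv(out / stage / "metric_table.tsv", sep="\t")
    else:
        for si, sub in enumerate(subjects):
            sub_rows = cohort[cohort["participant"] == sub]
            for hi, hemi in enumerate(("L", "R")):
                row = sub_rows[sub_rows["hemisphere"] == hemi].iloc[0]
                sseed = (config.seed * 100003 + si * 211 + hi * 7) % (2**31)
                gt = sc.assign_ground_truth(domain, row, effect_spec,
                                            seed=sseed)
                dwi = sc.simulate_dwi(gt, scheme, snr=config.snr,
                                      noise_model=config.noise_model,
                                      seed=sseed + 1, fit_mask=fit_mask)
                fits = {}
                if "dti" in config.models:
                    fits["dti"] = mf.fit_dti(dwi, scheme, fit_mask)
                if "sandi" in config.models:
                    fits["sandi"] = mf.fit_sandi(
                        dwi, scheme, fit_mask,
                        n_starts=config.sandi_starts,
                        prescreen=config.sandi_prescreen,
                        prior_weight=config.sandi_prior, seed=config.seed)
                if "noddi" in config.models:
                    fits["noddi"] = mf.fit_noddi(
                        dwi, scheme, fit_mask,
                        mu_init=fits["dti"].maps["e1"]
                        if "dti" in fits else None,
                        n_starts=config.noddi_starts, seed=config.seed)
                vols = {}
                if "sandi" in fits:
                    ok = fits["sandi"].ok
                    for m in ("f_neurite", "f_soma", "f_extracellular",
                              "Rsoma"):
                        v = fits["sandi"].maps[m].copy()
                        v[~ok] = np.nan
                        vols[m] = v
                if "dti" in fits:
                    ok = fits["dti"].ok
                    for m in ("MD", "FA"):
                        v = fits["dti"].maps[m].copy()
                        v[~ok] = np.nan
                        vols[m] = v
                    peaks = geo.primary_peak(
                        tensor_field=fits["dti"].maps["D"], mask=fit_mask)
                    cs = geo.cosine_similarity_maps(peaks, grads)
                    vols["long_axis"] = cs["long_axis"]
                    vols["tangential"] = cs["tangential"]
                    vols["radial"] = cs["radial"]
                if "noddi" in fits:
                    ok = fits["noddi"].ok
                    for src, name in (("f_neurite_noddi", "f_neurite_noddi"),
                                      ("ODI", "ODI")):
                        v = fits["noddi"].maps[src].copy()
                        v[~ok] = np.nan
                        vols[name] = v
                        if name not in vertex_maps:
                            vertex_maps[name] = np.full(
                                (len(subjects), 2, n_vert), np.nan)
                for m, vol in vols.items():
                    vertex_maps[m][si, hi] = geo.sample_to_surface(
                        vol, surface, domain)
                # macrostructure metrics: the shared domain geometry is
                # scaled per subject/hemisphere (seeded, no age trend) to
                # emulate inter-individual anatomical variability
                macro_rng = np.random.default_rng(sseed + 2)
                sc_t, sc_g, sc_v = np.exp(macro_rng.normal(0.0, 0.05, 3))
                vm_t = thickness * sc_t
                vm_g = gyrification * sc_g
                for pax, labels, lab_axis in (
                        ("subfield", geo.SUBFIELD_LABELS, "PD"),
                        ("ap", geo.AP_LABELS, "AP")):
                    parc = domain.parcel_labels(axis=lab_axis,
                                                n_bins=len(labels),
                                                use="psi")
                    for bi, lab in enumerate(labels):
                        rows.append({
                            "participant": sub, "age": row["age"],
                            "sex": row["sex"], "hemisphere": hemi,
                            "parcellation": pax, "parcel": lab,
                            "metric": "volume",
                            "value": float(np.sum(parc == bi)
                                           * domain.voxel_size ** 3 * sc_v)})
                for m, vm in (("thickness", vm_t), ("gyrification", vm_g)):
                    if m not in vertex_maps:
                        vertex_maps[m] = np.full((len(subjects), 2, n_vert),
                                                 np.nan)
                    vertex_maps[m][si, hi] = vm
                # parcel means for both parcellations
                for m, vm in {**{k: vertex_maps[k][si, hi]
                                 for k in vols},
                              "thickness": vm_t,
                              "gyrification": vm_g}.items():
                    for pax, labels, bands in (
                            ("subfield", geo.SUBFIELD_LABELS,
                             surface.subfield),
                            ("ap", geo.AP_LABELS, surface.ap_band)):
                        for bi, lab in enumerate(labels):
                            sel = (bands == bi) & np.isfinite(vm)
                            if not sel.any():
                                continue
                            rows.append({
                                "participant": sub, "age": row["age"],
                                "sex": row["sex"], "hemisphere": hemi,
                                "parcellation": pax, "parcel": lab,
                                "metric": m,
                                "value": float(vm[sel].mean())})
            logger.info("subject %s fitted (%d/%d)", sub, si + 1,
                        len(subjects))
        table_long = pd.DataFrame(rows)
        (out / stage).mkdir(parents=True, exist_ok=True)
        np.savez_compressed(out / stage / "vertex_maps.npz", **vertex_maps)
        table_long.to_csv(out / stage / "metric_table.tsv", sep="\t",
                          index=False)
        _write_manifest(out, stage, config)
    logger.info("stage fit done (%.1fs)", time.time() - t0)

    # ---- stage: statistics ----------------------------------------------
    stage = "stats"
    t0 = time.time()
    (out / stage).mkdir(parents=True, exist_ok=True)
    results = {"volume_table": volume_table}
    corr_frames, ftest_frames = [], []
    for pax in ("subfield", "ap"):
        tab = table_long[table_long["parcellation"] == pax].drop(
            columns=["parcellation"])
        if tab.empty:
            continue
        hemi_tests = ps.hemisphere_interaction_tests(tab)
        hemi_tests["parcellation"] = pax
        ftest_frames.append(hemi_tests.assign(family="age:hemisphere"))
        averaged = ps.hemisphere_average(tab, hemi_tests)
        for fam in ("age:sex", "age:parcel"):
            fr = ps.interaction_f_tests(averaged, fam)
            fr["parcellation"] = pax
            ftest_frames.append(fr.assign(family=fam))
        corr = ps.age_correlation_table(averaged)
        corr["parcellation"] = pax
        corr_frames.append(corr)
        results[f"metric_table_{pax}"] = averaged
    results["age_correlations"] = pd.concat(corr_frames, ignore_index=True)
    results["f_tests"] = pd.concat(ftest_frames, ignore_index=True)
    results["age_correlations"].to_csv(out / stage / "age_correlations.tsv",
                                       sep="\t", index=False)
    results["f_tests"].to_csv(out / stage / "f_tests.tsv", sep="\t",
                              index=False)

    # vertex-level: hemisphere-averaged maps -> age-contrast t-maps
    cohort_first = cohort[cohort["hemisphere"] == "L"].reset_index(drop=True)
    tmaps = {}
    grad_rows = []
    for m, arr in vertex_maps.items():
        avg = np.nanmean(arr, axis=1)
        if np.all(np.isnan(avg)) or np.nanstd(avg) == 0:
            continue
        tm = vs.vertex_glm_tmap(avg, cohort_first, metric=m)
        tmaps[m] = tm
        try:
            r_ap, r_pd, mean_t = vs.gradient_correlation(tm, surface)
            grad_rows.append({"metric": m, "r_ap": r_ap, "r_pd": r_pd,
                              "mean_abs_t": mean_t})
        except ValueError:
            pass
    results["gradient_correlations"] = pd.DataFrame(grad_rows)
    results["gradient_correlations"].to_csv(
        out / stage / "gradient_correlations.tsv", sep="\t", index=False)

    refs = vs.synthetic_reference_maps(surface, seed=config.seed + 77)
    results["reference_battery"] = vs.reference_map_battery(
        tmaps, refs, surface, n_perm=config.n_perm, seed=config.seed + 78)
    results["reference_battery"].to_csv(
        out / stage / "reference_battery.tsv", sep="\t", index=False)
    np.savez_compressed(out / stage / "tmaps.npz",
                        **{m: tm.t for m, tm in tmaps.items()})
    with open(out / stage / "summary.json", "w") as fh:
        json.dump({
            "n_participants": int(config.n_participants),
            "n_vertices": int(n_vert),
            "metrics": sorted(tmaps),
            "runtime_s": time.time() - t_start,
        }, fh, indent=2)
    _write_manifest(out, stage, config)
    logger.info("stage stats done (%.1fs)", time.time() - t0)

    results.update({"cohort": cohort, "domain": domain, "surface": surface,
                    "scheme": scheme, "tmaps": tmaps,
                    "vertex_maps": vertex_maps,
                    "metric_table": table_long})
    return results


# --------------------------------------------------------------------------
# Sign-recovery study (slim end-to-end replicate)
# --------------------------------------------------------------------------

def run_sign_recovery(seed: int, n_participants: int = 88, snr: float = 50.0,
                      grid_shape=(18, 12, 9), n_ap: int = 15, n_pd: int = 10,
                      sandi_starts: int = 3, sandi_prescreen: int = 64,
                      sandi_prior=(0.01, 0.01, 0.015, 0.03, 0.01),
                      domain_seed: int = 5) -> dict:
    """One replicate of the end-to-end developmental-sign study.

    Generates a full synthetic cohort with the default effect structure
    (neurite fraction increasing with age, extracellular fraction and
    diffusivity decreasing, soma fraction flat, and the neurite age slope
    growing along the long axis), simulates noisy multishell signals at
    the surface-sampled voxels, fits the soma/neurite and tensor models,
    and computes the parcel-level age correlations plus the
    gradient-correlation summary of the neurite age-contrast map.

    Uses the batched simulation and fitting paths (identical estimands to
    the per-subject pipeline) so a replicate runs in seconds.  Returns a
    dict with the subfield correlation table and (r_ap, r_pd) for the
    neurite map.
    """
    # one canonical synthetic anatomy shared by all replicates (chosen for
    # full surface validity and balanced long-axis parcel coverage);
    # replicates vary the cohort draw and the measurement noise
    domain = sc.generate_domain(grid_shape, seed=domain_seed, curved=True)
    for axis in ("AP", "PD", "IO"):
        geo.solve_laplace(domain, axis)
    surface = geo.build_midthickness_surface(domain, n_ap=n_ap, n_pd=n_pd)
    h = domain.voxel_size
    idx = np.floor(surface.vertices_native / h).astype(int)
    inb = np.all((idx >= 0) & (idx < np.array(domain.mask.shape)), axis=1)
    fit_mask = np.zeros(domain.mask.shape, dtype=bool)
    fit_mask[tuple(idx[inb].T)] = True
    fit_mask &= domain.mask

    cohort = sc.generate_cohort(sc.CohortSpec(
        n_participants=n_participants, seed=seed))
    effect_spec = sc.default_effect_spec()
    scheme = default_scheme()
    signals, _fields = sc.simulate_cohort_dwi(
        domain, cohort, effect_spec, scheme, fit_mask, snr=snr, seed=seed)

    # batched fits: stack every row's voxels into one pseudo-volume
    n_rows, nvox, n_vol = signals.shape
    stacked = signals.reshape(n_rows * nvox, 1, 1, n_vol)
    stack_mask = np.ones((n_rows * nvox, 1, 1), dtype=bool)
    # the fitter is a fixed (seed-0) function of the data so the estimator
    # does not vary across replicates
    sandi = mf.fit_sandi(stacked, scheme, stack_mask,
                         n_starts=sandi_starts, prescreen=sandi_prescreen,
                         polish=False, prior_weight=np.asarray(sandi_prior),
                         seed=0)
    dti = mf.fit_dti(stacked, scheme, stack_mask)
    metric_vox = {
        "f_neurite": sandi.maps["f_neurite"][:, 0, 0].reshape(n_rows, nvox),
        "f_extracellular":
            sandi.maps["f_extracellular"][:, 0, 0].reshape(n_rows, nvox),
        "f_soma": sandi.maps["f_soma"][:, 0, 0].reshape(n_rows, nvox),
        "MD": dti.maps["MD"][:, 0, 0].reshape(n_rows, nvox),
    }

    # vertex lookup into the fit-voxel list
    voxels = np.argwhere(fit_mask)
    lookup = {tuple(v): n for n, v in enumerate(voxels)}
    vert_vox = np.array([lookup.get(tuple(r), -1) if ok else -1
                         for r, ok in zip(idx, inb & surface.valid)])
    have = vert_vox >= 0

    # hemisphere-average (rows alternate L/R per participant)
    is_l = (cohort["hemisphere"] == "L").to_numpy()
    part = cohort["participant"].to_numpy()
    parts = list(dict.fromkeys(part))
    cohort_l = cohort[is_l].reset_index(drop=True)

    rows = []
    tmap_gradients = {}
    for metric, vox_vals in metric_vox.items():
        vert_vals = np.full((n_rows, surface.n_vertices), np.nan)
        vert_vals[:, have] = vox_vals[:, vert_vox[have]]
        with np.errstate(invalid="ignore"):
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                avg = np.stack([np.nanmean(vert_vals[part == p], axis=0)
                                for p in parts])
        # subfield parcel means and age correlations
        for bi, lab in enumerate(geo.SUBFIELD_LABELS):
            sel = (surface.subfield == bi) & have
            vals = np.nanmean(avg[:, sel], axis=1)
            r, p = _pearson_with_age(vals, cohort_l["age"].to_numpy())
            rows.append({"metric": metric, "parcel": lab, "r": r, "p": p})
        pooled = np.nanmean(avg[:, have], axis=1)
        r, p = _pearson_with_age(pooled, cohort_l["age"].to_numpy())
        rows.append({"metric": metric, "parcel": "all", "r": r, "p": p})
        tm = vs.vertex_glm_tmap(avg, cohort_l, metric=metric)
        try:
            r_ap, r_pd, mean_t = vs.gradient_correlation(tm, surface)
            tmap_gradients[metric] = {"r_ap": r_ap, "r_pd": r_pd,
                                      "mean_abs_t": mean_t}
        except ValueError:
            pass
    return {"correlations": pd.DataFrame(rows),
            "gradients": tmap_gradients, "n_voxels": int(nvox),
            "n_vertices": int(surface.n_vertices)}


def _pearson_with_age(values, ages):
    from scipy import stats as sps
    m = np.isfinite(values)
    if m.sum() < 3 or np.std(values[m]) == 0:
        return np.nan, np.nan
    r, p = sps.pearsonr(ages[m], values[m])
    return float(r), float(p)


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

def make_report(run_dir) -> Path:
    """Markdown report with figure panels from a completed run.

    Scatter panels per parcel and metric with regression lines and R
    annotations, the gradient-correlation scatter with the identity line,
    and the reference-map correlation heatmaps.  Missing metrics are
    noted and skipped rather than failing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    stats_dir = run / "stats"
    if not stats_dir.exists():
        raise FileNotFoundError("run directory has no stats stage output")
    corr = pd.read_csv(stats_dir / "age_correlations.tsv", sep="\t")
    if corr.empty:
        raise ValueError("empty results; nothing to report")
    table = pd.read_csv(run / "fit" / "metric_table.tsv", sep="\t")
    fig_dir = run / "report"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# hippodiff run report", ""]

    sub_tab = table[(table["parcellation"] == "subfield")]
    sub_tab = sub_tab.groupby(
        ["participant", "age", "sex", "parcel", "metric"],
        as_index=False)["value"].mean()
    metrics = sorted(sub_tab["metric"].unique())
    parcels = list(dict.fromkeys(sub_tab["parcel"]))
    for metric in metrics:
        mt = sub_tab[sub_tab["metric"] == metric]
        if mt.empty:
            lines.append(f"- panel for `{metric}` omitted: no data")
            continue
        fig, axes = plt.subplots(1, len(parcels),
                                 figsize=(3 * len(parcels), 2.8),
                                 sharey=True)
        axes = np.atleast_1d(axes)
        for ax, parcel in zip(axes, parcels):
            pt = mt[mt["parcel"] == parcel]
            ax.scatter(pt["age"], pt["value"], s=8, alpha=0.6)
            if len(pt) >= 3 and pt["value"].std() > 0:
                b, a = np.polyfit(pt["age"], pt["value"], 1)
                xs = np.linspace(pt["age"].min(), pt["age"].max(), 2)
                ax.plot(xs, a + b * xs, color="k", lw=1)
                row = corr[(corr["parcellation"] == "subfield")
                           & (corr["metric"] == metric)
                           & (corr["parcel"] == parcel)]
                if len(row):
                    ax.set_title(f"{parcel}\nR={row['r'].iloc[0]:.2f} "
                                 f"{row['stars'].iloc[0]}", fontsize=8)
            ax.set_xlabel("age (y)")
        axes[0].set_ylabel(metric)
        fig.tight_layout()
        fname = fig_dir / f"age_{metric.replace('/', '_')}.png"
        fig.savefig(fname, dpi=110)
        plt.close(fig)
        lines.append(f"![{metric}]({fname.name})")

    gc = pd.read_csv(stats_dir / "gradient_correlations.tsv", sep="\t")
    if not gc.empty:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot([0, 1], [0, 1], "k-", lw=1)
        ax.scatter(gc["r_ap"], gc["r_pd"], s=40 * gc["mean_abs_t"],
                   alpha=0.7)
        for _, r in gc.iterrows():
            ax.annotate(r["metric"], (r["r_ap"], r["r_pd"]), fontsize=6)
        ax.set_xlabel("|R| with AP gradient")
        ax.set_ylabel("|R| with PD gradient")
        fig.tight_layout()
        fig.savefig(fig_dir / "gradient_correlations.png", dpi=110)
        plt.close(fig)
        lines.append("![gradients](gradient_correlations.png)")

    battery = pd.read_csv(stats_dir / "reference_battery.tsv", sep="\t")
    if not battery.empty:
        piv_r = battery.pivot(index="tmap", columns="reference", values="r")
        piv_p = battery.pivot(index="tmap", columns="reference", values="p")
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for ax, piv, title, cmap in ((axes[0], piv_r, "Pearson R",
                                      "coolwarm"),
                                     (axes[1], piv_p, "spin-test p",
                                      "viridis_r")):
            im = ax.imshow(piv.to_numpy(), cmap=cmap, aspect="auto")
            ax.set_xticks(range(len(piv.columns)), piv.columns, rotation=90,
                          fontsize=7)
            ax.set_yticks(range(len(piv.index)), piv.index, fontsize=7)
            ax.set_title(title)
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(fig_dir / "reference_battery.png", dpi=110)
        plt.close(fig)
        lines.append("![battery](reference_battery.png)")

    # slope consistency note: slopes recomputed from the table must match
    slopes = []
    for metric in metrics:
        mt = sub_tab[sub_tab["metric"] == metric]
        for parcel in parcels:
            pt = mt[mt["parcel"] == parcel]
            if len(pt) >= 3 and pt["value"].std() > 0:
                b, _ = np.polyfit(pt["age"], pt["value"], 1)
                slopes.append({"metric": metric, "parcel": parcel,
                               "slope_per_year": float(b)})
    pd.DataFrame(slopes).to_csv(fig_dir / "fitted_slopes.tsv", sep="\t",
                                index=False)
    lines.append("")
    lines.append("Fitted per-parcel age slopes: `fitted_slopes.tsv`.")
    report = fig_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
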