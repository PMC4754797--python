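"""End-to-end driver: simulate -> GLM -> subtype -> group tests -> symptoms.

Each stage reads the tables earlier stages wrote into the run directory and
writes its own, so stages can also be run individually from the command
line.  Every output CSV starts with a comment header recording the seed and
a configuration hash; readers skip it via ``comment='#'``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, mixed_models, roi_glm, subtype_discovery, symptom_association
from . import synthetic_data as sdata
from . import task_design
from .config import PipelineConfig

log = logging.getLogger("naccsubtypes")

__all__ = ["run_pipeline", "stage_simulate", "stage_subtype", "stage_associate"]

_ROIS = ("left", "right")


def _specs_for(roi: str):
    return sdata.DEFAULT_LEFT_SPECS if roi == "left" else sdata.DEFAULT_RIGHT_SPECS


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig, sep=","):
    header = f"# seed={cfg.seed} config={cfg.config_hash()} version={__version__}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep=sep, index=False)


def _read(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix == ".tsv" else ","
    if not path.exists():
        raise FileNotFoundError(f"required pipeline table {path} is missing")
    return pd.read_csv(path, sep=sep, comment="#")


def _stage_seeds(seed: int, n: int = 16) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# stage 1: simulation (cohort, responses, task, GLM contrasts, symptoms)
# ---------------------------------------------------------------------------

def _glm_contrasts_for_subject(subj_events, planted, cfg: PipelineConfig, rng):
    """Forward-model BOLD per session from the planted contrast values, fit
    the GLM on percent-scaled, initial-volume-trimmed data and average the
    recovered contrasts across sessions."""
    glm = cfg.glm
    antic, outcome = planted
    results = []
    for trials in subj_events:
        true_betas = {"antic_$0": 0.2, "fb_$0_hit": 0.1, "fb_$0_miss": 0.1}
        for cond in sdata.CONDITIONS:
            true_betas[f"antic_{cond}"] = true_betas["antic_$0"] + antic[cond]
        for cond in ("+$0.25", "+$1.0"):
            true_betas[f"fb_{cond}_hit"] = true_betas["fb_$0_hit"] + outcome[cond]
        for cond in ("-$1.0", "-$0.25"):
            true_betas[f"fb_{cond}_miss"] = true_betas["fb_$0_miss"] + outcome[cond]

        motion = np.cumsum(rng.normal(0, 0.01, size=(glm.n_vols, 6)), axis=0)
        csf = np.cumsum(rng.normal(0, 0.02, size=glm.n_vols))
        design = roi_glm.build_design_matrix(trials, tr=glm.tr, n_vols=glm.n_vols,
                                             motion=motion, csf=csf)
        beta = np.array([true_betas.get(c, 0.0) for c in design.columns])
        # small true nuisance contributions the GLM must regress out
        beta[design.columns.index("csf")] = 0.05
        y = design.values @ beta + rng.normal(0, cfg.generator.bold_noise_sd, glm.n_vols)
        raw = 1000.0 * (1.0 + y / 100.0)
        scaled = roi_glm.scale_percent_change(raw)

        onsets = np.array([t.onset for t in trials])
        trimmed, shifted = roi_glm.drop_initial_volumes(scaled, glm.drop_initial,
                                                        tr=glm.tr, onsets=onsets)
        shifted_trials = [replace(t, onset=o) for t, o in zip(trials, shifted)]
        motion_t = motion[glm.drop_initial:]
        csf_t = csf[glm.drop_initial:]
        design_t = roi_glm.build_design_matrix(
            shifted_trials, tr=glm.tr, n_vols=glm.n_vols - glm.drop_initial,
            motion=motion_t, csf=csf_t)
        betas, _, _ = roi_glm.fit_glm(trimmed, design_t)
        results.append(betas)

    def contrast(b, name, base):
        if name in b.index and base in b.index:
            return float(b[name] - b[base])
        return np.nan  # empty hit/miss cell in this session

    antic_avg = {
        c: float(np.nanmean([contrast(b, f"antic_{c}", "antic_$0") for b in results]))
        for c in sdata.CONDITIONS
    }
    out_avg = {}
    for c, kind in (("-$1.0", "miss"), ("-$0.25", "miss"),
                    ("+$0.25", "hit"), ("+$1.0", "hit")):
        vals = [contrast(b, f"fb_{c}_{kind}", f"fb_$0_{kind}") for b in results]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out_avg[c] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan
    return antic_avg, out_avg


def stage_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator
    seeds = _stage_seeds(cfg.seed)
    log.info("simulate: cohort of %d HC / %d MDD", gen.n_hc, gen.n_mdd)

    cohort = sdata.generate_cohort(gen.n_hc, gen.n_mdd, seeds[0],
                                   gen.female_proportion, gen.age_range)
    labelled = {
        roi: sdata.assign_subtypes(cohort, _specs_for(roi), seeds[1 + i])
        for i, roi in enumerate(_ROIS)
    }
    cohort_df = sdata.cohort_to_frame(labelled["right"])
    _write(cohort_df, out / "cohort.csv", cfg)

    responses = pd.concat(
        [
            sdata.generate_response_patterns(labelled[roi], _specs_for(roi),
                                             gen.response_noise_sd, seeds[3 + i], roi=roi)
            for i, roi in enumerate(_ROIS)
        ],
        ignore_index=True,
    )
    _write(responses, out / "responses.csv", cfg)

    # task simulation + GLM recovery of the planted patterns
    events_frames = []
    if cfg.run_glm:
        log.info("simulate: GLM stage over %d subjects x %d sessions",
                 len(cohort), cfg.glm.n_sessions)
        rng = np.random.default_rng(seeds[5])
        contrast_rows = []
        resp_idx = responses.set_index(["subject", "roi", "phase", "condition"])["beta"]
        for si, subj in enumerate(cohort):
            subj_trials = []
            for sess in range(cfg.glm.n_sessions):
                trials = task_design.generate_trial_sequence(
                    cfg.glm.trials_per_condition, seed=seeds[6] + 97 * si + sess)
                trials, _rate = task_design.simulate_performance(
                    trials, {"mean": 0.28, "sd": 0.05}, initial_duration=0.3,
                    seed=seeds[7] + 97 * si + sess)
                subj_trials.append(trials)
                ev = task_design.trials_to_events(trials)
                ev.insert(0, "session", sess + 1)
                ev.insert(0, "subject", subj.id)
                events_frames.append(ev)
            for roi in _ROIS:
                planted = (
                    {c: resp_idx[(subj.id, roi, "anticipation", c)] for c in sdata.CONDITIONS},
                    {c: resp_idx[(subj.id, roi, "outcome", c)] for c in sdata.CONDITIONS},
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    antic, outc = _glm_contrasts_for_subject(subj_trials, planted, cfg, rng)
                for cond, v in antic.items():
                    contrast_rows.append((subj.id, roi, "anticipation", cond, v))
                for cond, v in outc.items():
                    contrast_rows.append((subj.id, roi, "outcome", cond, v))
        contrasts = pd.DataFrame(contrast_rows,
                                 columns=["subject", "roi", "phase", "condition", "value"])
        _write(contrasts, out / "contrasts.csv", cfg)
        events = pd.concat(events_frames, ignore_index=True)
        _write(events[["subject", "session", "onset", "duration", "trial_type",
                       "response_time", "outcome"]], out / "events.tsv", cfg, sep="\t")

    symptoms = sdata.generate_symptom_scores(
        labelled["right"], gen.symptom_effects, seeds[8],
        missing_rate=gen.missing_rate)
    _write(symptoms, out / "symptoms.csv", cfg)
    return {"n_subjects": len(cohort), "glm": bool(cfg.run_glm)}


# ---------------------------------------------------------------------------
# stage 2: subtype discovery per ROI + Table-2-style group model
# ---------------------------------------------------------------------------

def _pattern_table(out: Path, cfg: PipelineConfig) -> pd.DataFrame:
    """GLM-recovered contrasts when available, directly simulated patterns
    otherwise."""
    src = out / "contrasts.csv"
    if src.exists():
        df = _read(src).rename(columns={"value": "beta"})
    else:
        df = _read(out / "responses.csv")
    return df


def stage_subtype(cfg: PipelineConfig, phase: str = "anticipation",
                  rois: tuple[str, ...] = _ROIS) -> dict:
    out = Path(cfg.output_dir)
    patterns = _pattern_table(out, cfg)
    cohort = _read(out / "cohort.csv")
    summary = {}
    pca_rows, score_rows, cluster_rows, sel_rows, anova_rows = [], [], [], [], []
    for roi in rois:
        X, subjects = sdata.patterns_to_matrix(patterns, phase=phase, roi=roi)
        long = (patterns[(patterns["phase"] == phase) & (patterns["roi"] == roi)]
                .rename(columns={"beta": "response"})
                .merge(cohort[["subject", "diagnosis", "age", "gender"]], on="subject"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            solution, pca = subtype_discovery.discover_subtypes(
                X, subjects, long, k_max=cfg.clustering.k_max,
                alpha=cfg.clustering.alpha)
        for i, (pct, se) in enumerate(zip(pca.explained_percent, pca.jackknife_se)):
            pca_rows.append((roi, i + 1, pct, se))
        for subj, (pc1, pc2) in zip(subjects, pca.loo_scores):
            score_rows.append((roi, subj, pc1, pc2))
        tab = solution.selection_table.copy()
        tab.insert(0, "roi", roi)
        sel_rows.append(tab)
        summary[roi] = {
            "n_clusters": solution.n_clusters,
            "pc1_percent": float(pca.explained_percent[0]),
            "cluster_effect_p": solution.cluster_effect_p,
        }
        if not solution.selected:
            log.warning("subtype: no significant cluster level for %s ROI", roi)
            continue
        for subj in subjects:
            cluster_rows.append((subj, solution.labels[subj], roi))

        model_df = long.merge(
            solution.labels.rename("subtype").rename_axis("subject").reset_index(),
            on="subject")
        spec = mixed_models.LmmSpec(
            "response",
            ["subtype", "condition", "diagnosis", "age", "gender",
             "subtype:condition", "subtype:diagnosis", "condition:diagnosis",
             "subtype:condition:diagnosis"],
            "subject")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = mixed_models.fit_lmm(model_df, spec)
            ftab = fit.f_table.reset_index()
            ftab.insert(0, "roi", roi)
            anova_rows.append(ftab)
        except ValueError as exc:
            log.warning("subtype: group model failed for %s ROI: %s", roi, exc)

    _write(pd.DataFrame(pca_rows, columns=["roi", "component", "percent", "se"]),
           out / "pca.csv", cfg)
    _write(pd.DataFrame(score_rows, columns=["roi", "subject", "pc1", "pc2"]),
           out / "scores.csv", cfg)
    _write(pd.DataFrame(cluster_rows, columns=["subject", "subtype", "roi"]),
           out / "clusters.csv", cfg)
    _write(pd.concat(sel_rows, ignore_index=True), out / "selection.csv", cfg)
    if anova_rows:
        _write(pd.concat(anova_rows, ignore_index=True), out / "anova.csv", cfg)
    return summary


# ---------------------------------------------------------------------------
# stage 3: symptom association (MDD subjects, right-ROI subtypes)
# ---------------------------------------------------------------------------

def stage_associate(cfg: PipelineConfig, roi: str = "right") -> dict:
    out = Path(cfg.output_dir)
    cohort = _read(out / "cohort.csv")
    symptoms = _read(out / "symptoms.csv")
    clusters = _read(out / "clusters.csv")
    clusters = clusters[clusters["roi"] == roi] if "roi" in clusters.columns else clusters

    mdd = cohort[cohort["diagnosis"] == "MDD"]
    if mdd.empty:
        log.warning("associate: no MDD subjects; stage skipped")
        return {"skipped": "no MDD subjects"}
    if clusters.empty:
        log.warning("associate: no cluster solution for %s ROI; stage skipped", roi)
        return {"skipped": f"no cluster solution for {roi} ROI"}

    df = mdd[["subject", "age", "gender"]].merge(clusters[["subject", "subtype"]],
                                                 on="subject")
    sym = symptoms[symptoms["subject"].isin(df["subject"])].set_index("subject")
    sym = sym.loc[df["subject"]]
    if sym.isna().any().any():
        bad = sym.index[sym.isna().any(axis=1)]
        log.warning("associate: dropping %d subjects with missing symptom values",
                    len(bad))
        sym = sym.drop(index=bad)
        df = df[~df["subject"].isin(bad)]
    X = sym[sdata.ALL_ITEMS]
    y = df.set_index("subject").loc[X.index, "subtype"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace = symptom_association.rfe(X, y, min_variables=cfg.sda.min_variables)
        model = symptom_association.fit_sda(X[trace.best_set], y)
        assoc = symptom_association.discriminant_correlations(
            X[trace.best_set], model, alpha=cfg.sda.alpha)
        flagged = sorted(assoc.loc[assoc["bonferroni_significant"], "item"].unique())
        posthoc = symptom_association.posthoc_symptom_tests(
            sym.reset_index(), df.set_index("subject")["subtype"],
            cohort[["subject", "age", "gender"]], items=flagged or None,
            alpha=cfg.sda.alpha)

    _write(trace.steps, out / "rfe_trace.csv", cfg)
    _write(assoc, out / "associations.csv", cfg)
    _write(posthoc, out / "posthoc.csv", cfg)
    return {
        "n_mdd": int(len(y)),
        "best_set_size": len(trace.best_set),
        "best_loo_accuracy": trace.best_accuracy,
        "bonferroni_items": flagged,
        "posthoc_significant": posthoc.loc[posthoc["corrected_significant"],
                                           "item"].tolist(),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write ``manifest.json``.

    Raises the underlying exception with the failing stage named; tables
    written by earlier stages are left in place.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "stages": {},
    }
    for name, fn in (("simulate", stage_simulate),
                     ("subtype", stage_subtype),
                     ("associate", stage_associate)):
        try:
            manifest["stages"][name] = fn(cfg)
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest["files"] = sorted(p.name for p in out.iterdir() if p.suffix in
                               (".csv", ".tsv", ".json"))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
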