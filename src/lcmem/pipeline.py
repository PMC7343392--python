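"""Full-analysis orchestration: behavior → physiology → spectra → associations.

``run_all`` executes the whole chain on a :class:`~lcmem.dataset.StudyDataset`
and returns a results bundle (plain DataFrames and dicts); with an output
directory it also writes every table as TSV plus a JSON summary and a
Markdown report.  Every output carries the configuration hash and seed for
provenance, and the run is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from lcmem import association_stats as ast
from lcmem import behavioral_sdt as sdt
from lcmem import physio_hrv as hrv
from lcmem import spectral_coherence as spec
from lcmem.config import RunConfig, child_rng
from lcmem.dataset import StudyDataset, load_study  # noqa: F401  (load_study re-exported)

log = logging.getLogger("lcmem")

_NS_NULL, _NS_BAND, _NS_BOOT = 100, 101, 102

#: pairs examined with partial coherence (conditioned on the others)
MTL_SET = ("lc", "amygdala", "hippocampus")


def _config_hash(dataset: StudyDataset, config: RunConfig) -> str:
    payload = json.dumps(
        {"cohort": asdict(dataset.config) | {"stages": list(dataset.config.stages)},
         "run": config.to_dict()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(dataset: StudyDataset, config: RunConfig | None = None, out: str | Path | None = None) -> dict:
    """Run the complete analysis chain; see module docstring."""
    config = config or RunConfig()
    t0 = time.time()
    errors: list[str] = []
    results: dict = {
        "provenance": {
            "config_hash": _config_hash(dataset, config),
            "seed": config.seed,
            "n_subjects": dataset.config.n_subjects,
            "stages": list(dataset.config.stages),
        }
    }

    # ---- behavior ----------------------------------------------------
    try:
        scores = sdt.memory_scores(dataset.trials)
        results["behavior_scores"] = scores
        results["behavior_summary"] = sdt.summarize_behavior(scores)
    except Exception as exc:  # noqa: BLE001 — stage failures are reported, not raised
        errors.append(f"behavior: {exc}")
        scores = None
    log.info("behavior done (%.1fs)", time.time() - t0)

    # ---- physiology --------------------------------------------------
    cohort = dataset.config
    working_dt = 1.0 / config.working_rate
    grid = spec.SpectralGrid(n_bins=config.n_bins, fmax=config.fmax, overlap=config.overlap)
    native_nyquist = min(cohort.nyquist, config.fmax)
    measures: list[dict] = []
    hrv_series: dict[tuple[int, str], hrv.HRVSeries] = {}
    rejections: list[dict] = []
    try:
        for (subject, stage), beats in sorted(dataset.beats.items()):
            cleaned, report = hrv.clean_beats(
                beats, bpm_bounds=config.bpm_bounds, rel_threshold=config.adaptive_threshold
            )
            rejections.append(
                {"subject": subject, "stage": stage, "n_beats": report.n_beats,
                 "n_rate_rejected": report.n_rate_rejected,
                 "n_adaptive_rejected": report.n_adaptive_rejected,
                 "n_gaps": report.n_gaps, "usable": report.usable}
            )
            if not report.usable:
                continue
            measures.append({"subject": subject, "stage": stage, "measure": "rmssd",
                             "value": hrv.stage_rmssd(cleaned)})
            try:
                series = hrv.interpolate_hrv(cleaned, working_dt, duration=cohort.duration)
            except hrv.PhysioError:
                continue
            if hrv.exclusion_check(series, config.missing_cutoff):
                hrv_series[(subject, stage)] = series
        saa_rows = hrv.delta_saa(dataset.saa)
        measures.extend(saa_rows.to_dict("records"))
        for (subject, stage), frame in sorted(dataset.roi.items()):
            for channel in ("lc", "reference"):
                measures.append({"subject": subject, "stage": stage,
                                 "measure": f"{channel}_variance",
                                 "value": float(np.var(frame[channel].to_numpy(float)))})
    except Exception as exc:  # noqa: BLE001
        errors.append(f"physio: {exc}")
    log.info("physio done (%.1fs)", time.time() - t0)

    # ---- spectra -----------------------------------------------------
    profiles: dict[tuple[int, str], dict] = {}
    try:
        for (subject, stage), frame in sorted(dataset.roi.items()):
            if (subject, stage) not in hrv_series:
                continue
            t = frame["time"].to_numpy(float)
            channels = {
                name: spec.resample_series(t, frame[name].to_numpy(float), config.working_rate,
                                           duration=cohort.duration)
                for name in ("lc", "reference", "amygdala", "hippocampus", "entorhinal")
            }
            channels["hrv"] = hrv_series[(subject, stage)].values
            matrix = spec.cross_spectra(channels, grid)
            profiles[(subject, stage)] = {
                "matrix": matrix,
                "lc_hrv": spec.coherence_profile(matrix, ("lc", "hrv")),
                "reference_hrv": spec.coherence_profile(matrix, ("reference", "hrv")),
            }
        baseline_stage = cohort.stages[0]
        baseline_profiles = [
            entry["lc_hrv"] for (subj, stg), entry in sorted(profiles.items())
            if stg == baseline_stage
        ]
        band = spec.band_of_max_coherence(
            baseline_profiles, n_boot=config.n_boot,
            seed=int(child_rng(config.seed, _NS_BAND).integers(2**31)),
            fmin=0.01, fmax=native_nyquist,
        )
        results["band"] = {"median": band.median, "lower": band.lower, "upper": band.upper,
                           "n_boot": band.n_boot}
        coh_rows = []
        for (subject, stage), entry in sorted(profiles.items()):
            for pair_name in ("lc_hrv", "reference_hrv"):
                med_msc, med_phase = spec.band_summary(entry[pair_name], band)
                measures.append({"subject": subject, "stage": stage,
                                 "measure": f"{pair_name}_coherence", "value": med_msc})
                measures.append({"subject": subject, "stage": stage,
                                 "measure": f"{pair_name}_phase", "value": med_phase})
            prof = entry["lc_hrv"]
            for f, c, ph in zip(prof.freqs, prof.msc, prof.phase):
                if 0.0 < f <= native_nyquist:
                    coh_rows.append({"subject": subject, "stage": stage, "freq": float(f),
                                     "msc": float(c), "phase": float(ph)})
        results["coherence_long"] = pd.DataFrame(coh_rows)
    except Exception as exc:  # noqa: BLE001
        errors.append(f"spectra: {exc}")
        profiles = {}
    log.info("spectra done (%.1fs)", time.time() - t0)

    # ---- surrogate nulls and partial coherence -----------------------
    try:
        if profiles and "band" in results:
            band_tuple = (results["band"]["lower"], results["band"]["upper"])
            observed, null_meds, subj_ids = [], [], []
            for (subject, stage), entry in sorted(profiles.items()):
                if stage != cohort.stages[0]:
                    continue
                frame = dataset.roi[(subject, stage)]
                t = frame["time"].to_numpy(float)
                lc1 = spec.resample_series(t, frame["lc"].to_numpy(float), config.working_rate,
                                           duration=cohort.duration)
                null = spec.coherence_null(
                    lc1, hrv_series[(subject, stage)].values, band_tuple,
                    n_surrogates=config.n_surrogates,
                    seed=child_rng(config.seed, _NS_NULL, subject), grid=grid,
                )
                observed.append(spec.band_summary(entry["lc_hrv"], band_tuple)[0])
                null_meds.append(float(np.median(null.values)))
                subj_ids.append(subject)
            z, p = spec.partial_coherence_test(np.array(observed), np.array(null_meds))
            results["coherence_null_test"] = {
                "stage": cohort.stages[0], "pair": "lc_hrv", "z": z, "p": p,
                "n_subjects": len(observed),
            }

            partial_rows = []
            for (subject, stage), entry in sorted(profiles.items()):
                partials = spec.partial_coherence_all(_submatrix(entry["matrix"], MTL_SET))
                for (a, b), values in partials.items():
                    sel = (entry["matrix"].freqs >= band_tuple[0]) & (
                        entry["matrix"].freqs <= band_tuple[1])
                    partial_rows.append({"subject": subject, "stage": stage, "pair": f"{a}-{b}",
                                         "partial_coherence": float(np.nanmedian(values[sel]))})
            results["partial_coherence"] = pd.DataFrame(partial_rows)
    except Exception as exc:  # noqa: BLE001
        errors.append(f"surrogates: {exc}")
    log.info("surrogates done (%.1fs)", time.time() - t0)

    # ---- association statistics --------------------------------------
    stage_measures = pd.DataFrame(measures)
    results["stage_measures"] = stage_measures
    try:
        wide = stage_measures.pivot_table(index=["subject", "stage"], columns="measure",
                                          values="value", aggfunc="first").reset_index()
        results["stage_measures_wide"] = wide
        assoc_rows = []
        boot_seed = int(child_rng(config.seed, _NS_BOOT).integers(2**31))
        for x, y in (("delta_saa", "rmssd"), ("lc_variance", "rmssd"),
                     ("lc_hrv_coherence", "delta_saa"), ("reference_hrv_coherence", "delta_saa")):
            if x not in wide.columns or y not in wide.columns:
                continue
            try:
                rm = ast.rmcorr(wide, x, y)
                ci = ast.rmcorr_bootstrap(wide, x, y, n_boot=config.n_boot, seed=boot_seed)
                assoc_rows.append({"kind": "rmcorr", "x": x, "y": y, "estimate": rm.r,
                                   "df": rm.df, "p": rm.p, "ci_low": ci[0], "ci_high": ci[1],
                                   "n_subjects": rm.n_subjects,
                                   "n_observations": rm.n_observations})
            except ast.StatsError as exc:
                errors.append(f"rmcorr {x}~{y}: {exc}")
        if scores is not None and "delta_saa" in wide.columns:
            cons = wide[wide["stage"] == "consolidation"][["subject", "delta_saa"]]
            merged = cons.merge(scores[["subject", "adjusted_emotional_score"]], on="subject")
            if len(merged) >= 3:
                r, p = ast.pearson(merged["delta_saa"], merged["adjusted_emotional_score"])
                assoc_rows.append({"kind": "pearson", "x": "delta_saa_consolidation",
                                   "y": "adjusted_emotional_score", "estimate": r, "p": p,
                                   "n_observations": len(merged)})
        assoc = pd.DataFrame(assoc_rows)
        if len(assoc):
            assoc["p_fdr"] = ast.fdr_adjust(assoc["p"].to_numpy())
        results["associations"] = assoc

        lmm_out = {}
        for outcome in ("delta_saa", "rmssd"):
            if outcome not in wide.columns:
                continue
            fit = ast.stage_lmm(wide, ast.LmmSpec(outcome=outcome))
            lmm_out[outcome] = {
                "params": fit.params.to_dict(),
                "se": fit.se.to_dict(),
                "p": fit.p.to_dict(),
                "df": fit.df,
                "contrasts": ast.marginal_contrasts(fit).to_dict("records"),
            }
        results["lmm"] = lmm_out

        if "coherence_long" in results and len(results["coherence_long"]):
            cfit = ast.stage_lmm(
                results["coherence_long"],
                ast.LmmSpec(outcome="msc", predictor="freq", interaction=True),
            )
            ros_out = []
            stages = list(cohort.stages)
            for i in range(len(stages)):
                for j in range(i + 1, len(stages)):
                    try:
                        ros = ast.region_of_significance(cfit, stages[i], stages[j],
                                                         alpha=config.alpha)
                        ros_out.append({"stage_a": stages[i], "stage_b": stages[j],
                                        "boundaries": list(ros.boundaries),
                                        "significant": ros.significant})
                    except ast.StatsError as exc:
                        errors.append(f"ros {stages[i]}-{stages[j]}: {exc}")
            results["region_of_significance"] = ros_out
            results["coherence_lmm"] = {"params": cfit.params.to_dict(), "df": cfit.df}
    except Exception as exc:  # noqa: BLE001
        errors.append(f"associations: {exc}")
    log.info("associations done (%.1fs)", time.time() - t0)

    results["rejections"] = pd.DataFrame(rejections)
    results["errors"] = errors
    results["provenance"]["wall_time_s"] = round(time.time() - t0, 2)
    if out is not None:
        write_results(results, out)
    return results


def _submatrix(matrix: spec.SpectralMatrix, labels: tuple[str, ...]) -> spec.SpectralMatrix:
    idx = [matrix.index(name) for name in labels]
    return spec.SpectralMatrix(
        freqs=matrix.freqs,
        values=matrix.values[np.ix_(range(len(matrix.freqs)), idx, idx)],
        labels=list(labels),
        n_windows=matrix.n_windows,
        fs=matrix.fs,
    )


# --------------------------------------------------------------------------
# persistence and report
# --------------------------------------------------------------------------

def write_results(results: dict, out: str | Path) -> Path:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stamp = results["provenance"]
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            frame = obj.copy()
            frame.insert(0, "config_hash", stamp["config_hash"])
            frame.insert(1, "seed", stamp["seed"])
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    scalars = {k: v for k, v in results.items() if not isinstance(v, pd.DataFrame)}
    with open(out / "results.json", "w") as fh:
        json.dump(scalars, fh, indent=1, default=_json_default)
    (out / "report.md").write_text(make_report(results))
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _fmt(value, digits=3) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return "–"
    return f"{value:.{digits}f}"


def make_report(results: dict) -> str:
    """Human-readable Markdown summary assembled from the computed tables.

    Numbers are taken verbatim from the results bundle — nothing is
    recomputed — so the report always agrees with the TSV outputs, and
    regenerating it is idempotent.
    """
    stamp = results["provenance"]
    lines = [
        "# LC-memory pipeline report",
        "",
        f"- config hash: `{stamp['config_hash']}`  seed: {stamp['seed']}",
        f"- subjects: {stamp['n_subjects']}  stages: {', '.join(stamp['stages'])}",
        "",
    ]
    summary = results.get("behavior_summary")
    if summary is not None and len(summary):
        lines += ["## Behavioral performance", "",
                  "| Measure | Emotional median (IQR) | Neutral median (IQR) | Statistic | p |",
                  "|---|---|---|---|---|"]
        for _, row in summary.iterrows():
            lines.append(
                f"| {row['measure']} | {_fmt(row['emotional_median'], 2)} "
                f"({_fmt(row['emotional_iqr_low'], 2)}, {_fmt(row['emotional_iqr_high'], 2)}) | "
                f"{_fmt(row['neutral_median'], 2)} ({_fmt(row['neutral_iqr_low'], 2)}, "
                f"{_fmt(row['neutral_iqr_high'], 2)}) | {_fmt(row['statistic'], 2)} | "
                f"{_fmt(row['p_value'], 4)} |"
            )
        lines.append("")
    band = results.get("band")
    if band:
        lines += ["## Coherence band", "",
                  f"Median max-coherence frequency {_fmt(band['median'])} Hz "
                  f"(95% CI [{_fmt(band['lower'])}, {_fmt(band['upper'])}], "
                  f"{band['n_boot']} bootstrap resamples).", ""]
    null_test = results.get("coherence_null_test")
    if null_test:
        lines += [f"LC-HRV coherence vs AR(1)-surrogate null ({null_test['stage']}): "
                  f"Z = {_fmt(null_test['z'], 2)}, p = {_fmt(null_test['p'], 4)} "
                  f"(n = {null_test['n_subjects']}).", ""]
    measures = results.get("stage_measures_wide")
    if measures is not None and len(measures):
        lines += ["## Stage measures (cohort medians)", "",
                  "| Measure | " + " | ".join(stamp["stages"]) + " |",
                  "|---|" + "---|" * len(stamp["stages"])]
        for measure in ("delta_saa", "rmssd", "lc_variance", "lc_hrv_coherence"):
            if measure not in measures.columns:
                continue
            cells = []
            for stage in stamp["stages"]:
                sub = measures[measures["stage"] == stage][measure]
                cells.append(_fmt(float(sub.median()) if len(sub) else float("nan"), 2))
            lines.append(f"| {measure} | " + " | ".join(cells) + " |")
        lines.append("")
    assoc = results.get("associations")
    if assoc is not None and len(assoc):
        lines += ["## Associations", "",
                  "| Kind | x | y | estimate | p | p (FDR) | 95% CI |", "|---|---|---|---|---|---|---|"]
        for _, row in assoc.iterrows():
            ci = ""
            if "ci_low" in row and np.isfinite(row.get("ci_low", np.nan)):
                ci = f"[{_fmt(row['ci_low'], 2)}, {_fmt(row['ci_high'], 2)}]"
            lines.append(f"| {row['kind']} | {row['x']} | {row['y']} | {_fmt(row['estimate'])} | "
                         f"{_fmt(row['p'], 4)} | {_fmt(row.get('p_fdr', float('nan')), 4)} | {ci} |")
        lines.append("")
    ros = results.get("region_of_significance")
    if ros:
        lines += ["## Regions of significance (coherence ~ frequency × stage)", ""]
        for entry in ros:
            bounds = ", ".join(f"{b:.3f}" for b in entry["boundaries"]) or "none"
            lines.append(f"- {entry['stage_a']} vs {entry['stage_b']}: boundaries [{bounds}] Hz; "
                         f"significant {entry['significant']}")
        lines.append("")
    if results.get("errors"):
        lines += ["## Stage failures", ""] + [f"- {e}" for e in results["errors"]] + [""]
    return "\n".join(lines)
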