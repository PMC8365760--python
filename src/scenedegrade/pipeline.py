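"""End-to-end orchestration: generate -> degrade -> classify/simulate -> fit -> compare.

A :class:`RunConfig` pins every free choice (image geometry, level grids,
fit settings, comparison settings, master seed); :func:`run_pipeline` then
executes the stages and writes fit tables, comparison tables, agreement
tables and a machine-readable summary, each stamped with the config hash
and seed, so a run is a pure function of its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare_stats, degrade, psychometrics, synthetic_data

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("scenedegrade")

#: simulated-human Weibull scales chosen so the 80% thresholds fall inside
#: the 4-level grids each condition uses (clarity units)
DEFAULT_HUMAN_ALPHA = {"lowpass": 11.1, "highpass": 0.0159, "phase_scramble": 0.428}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the code."""

    out_dir: str = "scenedegrade_run"
    n_per_class: int = 64
    height_px: int = 323
    width_px: int = 431
    class_signal: float = 60.0
    spectral_slope: float = 1.0
    kinds: tuple[str, ...] = ("lowpass", "highpass", "phase_scramble")
    levels: dict = field(default_factory=lambda: {k: list(v) for k, v in
                                                  degrade.HUMAN_LEVELS.items()})
    whiten_input: bool = False
    n_observers: int = 4
    criterion: float = 0.80
    n_boot: int = 2000
    m_comparisons: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not 0.5 < self.criterion < 1.0:
            raise ValueError("criterion must lie in (0.5, 1)")
        if self.n_per_class < 1 or self.n_observers < 1:
            raise ValueError("need at least one image per class and one observer")
        for kind in self.kinds:
            if not self.levels.get(kind):
                raise ValueError(f"empty level grid for kind {kind!r}")

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land does not change them
        return hashlib.sha1(json.dumps(payload, sort_keys=True,
                                       default=str).encode()).hexdigest()[:12]


def _simulate_humans_on_manifest(manifest: pd.DataFrame, categories: dict,
                                 n_observers: int, seed: int) -> pd.DataFrame:
    """Simulated human decisions for every degraded stimulus, aligned by id."""
    rows = []
    ss = np.random.SeedSequence([seed, 0x48])
    rngs = [np.random.default_rng(s) for s in ss.spawn(n_observers)]
    for obs in range(n_observers):
        rng = rngs[obs]
        # small between-observer variation around the default sensitivity
        jitter = {k: v * float(np.exp(rng.normal(0.0, 0.08)))
                  for k, v in DEFAULT_HUMAN_ALPHA.items()}
        for row in manifest.itertuples():
            x = psychometrics.clarity_axis(row.kind, row.level)
            p = psychometrics.weibull(max(x, 1e-12), jitter[row.kind], 3.0)
            true_cat = categories[row.source]
            correct = bool(rng.random() < p)
            other = "vehicle" if true_cat == "animal" else "animal"
            rows.append({"observer_id": f"human_{obs:02d}",
                         "stimulus_id": row.stimulus_id,
                         "true_category": true_cat,
                         "degradation_kind": row.kind, "level": row.level,
                         "decision": true_cat if correct else other,
                         "correct": correct})
    return pd.DataFrame(rows)


def _classify_stimuli(images: dict, categories: dict, manifest: pd.DataFrame,
                      stimuli: dict) -> pd.DataFrame:
    """Score every degraded stimulus with the spectral stand-in classifier."""
    train_ids = [i for i in images if i not in
                 set(manifest["source"].unique())]
    scores = synthetic_data.spectral_feature_classifier(
        {i: images[i] for i in train_ids},
        {i: categories[i] for i in train_ids},
        stimuli)
    rows = []
    for row in manifest.itertuples():
        s = float(scores[row.stimulus_id])
        decision = "animal" if s >= 0.5 else "vehicle"
        true_cat = categories[row.source]
        rows.append({"observer_id": "classifier",
                     "stimulus_id": row.stimulus_id,
                     "true_category": true_cat,
                     "degradation_kind": row.kind, "level": row.level,
                     "decision": decision, "correct": decision == true_cat,
                     "score": s})
    return pd.DataFrame(rows)


def _compare_tables(human: pd.DataFrame, classifier: pd.DataFrame,
                    m: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per kind x level accuracy ratios and agreement ratios.

    Human counts pool all observers' trials at that condition; observed
    agreement is computed per observer against the classifier and averaged.
    """
    acc_rows, agr_rows = [], []
    cls = classifier.set_index("stimulus_id")
    for (kind, level), grp_c in classifier.groupby(["degradation_kind", "level"]):
        grp_h = human[(human["degradation_kind"] == kind)
                      & (human["level"] == level)]
        pair = compare_stats.CountPair(
            k_c=int(grp_c["correct"].sum()), n_c=len(grp_c),
            k_h=int(grp_h["correct"].sum()), n_h=len(grp_h))
        res = compare_stats.accuracy_ratio(pair, m_comparisons=m)
        acc_rows.append({"kind": kind, "level": level, "ratio": res.ratio,
                         "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                         "p_raw": res.p_raw, "p_corrected": res.p_corrected})
        obs_props, matches, n_images = [], 0, 0
        for _, grp_o in grp_h.groupby("observer_id"):
            joined = grp_o.join(cls["decision"], on="stimulus_id",
                                rsuffix="_c")
            prop, cnt = compare_stats.observed_agreement(
                joined["decision"].to_numpy(), joined["decision_c"].to_numpy())
            obs_props.append(prop)
            matches += cnt
            n_images += len(joined)
        agr = compare_stats.agreement_ratio(matches, n_images, pair,
                                            m_comparisons=m)
        agr_rows.append({"kind": kind, "level": level,
                         "observed": float(np.mean(obs_props)),
                         "expected": agr.expected, "ratio": agr.ratio,
                         "ci_low": agr.ci95[0], "ci_high": agr.ci95[1],
                         "p_raw": agr.p_raw, "p_corrected": agr.p_corrected})
    return pd.DataFrame(acc_rows), pd.DataFrame(agr_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    timings = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("generate")
    params = synthetic_data.SyntheticImageParams(
        config.height_px, config.width_px, config.spectral_slope,
        config.class_signal)
    images, img_manifest = synthetic_data.gen_two_class_set(
        config.n_per_class, params, config.seed)
    categories = dict(zip(img_manifest["image_id"], img_manifest["category"]))
    if config.whiten_input:
        images = {i: degrade.normalize_mean_sd(degrade.whiten(im))
                  for i, im in images.items()}
    done("generate")

    stage("degrade")
    # even-index images train the classifier, odd-index images are tested
    ids = list(images)
    test_ids = ids[1::2]
    manifest = degrade.build_stimulus_set(
        test_ids, config.kinds, config.levels, config.seed)
    stimuli = {}
    for row in manifest.itertuples():
        stim = degrade.apply_degradation(
            images[row.source],
            degrade.DegradationSpec(row.kind, row.level, row.seed))
        stimuli[row.stimulus_id] = stim
    manifest.to_csv(out / "stimulus_manifest.csv", index=False)
    done("degrade")

    stage("classify")
    cls_trials = _classify_stimuli(images, categories, manifest, stimuli)
    done("classify")

    stage("simulate")
    human_trials = _simulate_humans_on_manifest(
        manifest, categories, config.n_observers, config.seed)
    trials = pd.concat([human_trials, cls_trials.drop(columns="score")])
    trials.to_csv(out / "trials.csv", index=False)
    done("simulate")

    stage("fit")
    fits = psychometrics.fit_table(trials, n_boot=config.n_boot,
                                   seed=config.seed)
    for key, value in stamp.items():
        fits[key] = value
    fits.to_csv(out / "fits.csv", index=False)
    done("fit")

    stage("compare")
    acc, agr = _compare_tables(human_trials, cls_trials, config.m_comparisons)
    for df in (acc, agr):
        for key, value in stamp.items():
            df[key] = value
    acc.to_csv(out / "accuracy_ratios.csv", index=False)
    agr.to_csv(out / "agreement_ratios.csv", index=False)
    done("compare")

    summary = {
        **stamp,
        "n_images": len(images),
        "n_stimuli": len(manifest),
        "n_trials": len(trials),
        "fits": fits.drop(columns=["config_hash", "seed"]).to_dict("records"),
        "stage_seconds": timings,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
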