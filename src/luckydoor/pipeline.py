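"""End-to-end orchestration: one config, one seed, one reproducible run.

``run_full_pipeline`` executes cohort generation -> behavioral analysis ->
EEG simulation -> preprocessing -> group statistics, writing every
intermediate table plus a manifest with SHA-256 checksums. All randomness
derives from one seed expanded into per-stage child seeds, so a re-run with
the same config is checksum-identical and individual stages can be re-seeded
in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import group_stats as gs
from . import io as ldio
from . import preprocess as pp
from .cohort import (
    BehaviorEffectConfig,
    CovariateEffectConfig,
    GROUPS,
    generate_cohort_behavior,
    generate_covariates,
)
from .eeg_sim import EegEffectConfig, simulate_epochs
from .montage import Montage, PARIETAL_CLUSTER, default_montage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable to YAML."""

    seed: int = 0
    group_sizes: tuple[int, int, int] = (27, 21, 27)
    n_trials: int = 40
    covariate_effect: CovariateEffectConfig = field(default_factory=CovariateEffectConfig)
    behavior_effect: BehaviorEffectConfig = field(default_factory=BehaviorEffectConfig)
    eeg_effect: EegEffectConfig = field(default_factory=EegEffectConfig)
    #: subjects per group without usable EEG (technical loss), drawn at random
    eeg_missing: tuple[int, int, int] = (8, 7, 3)
    sfreq: float = 250.0
    montage_path: str | None = None  # None -> default 24-channel 10-20 subset
    bands: tuple[str, ...] = ("theta", "alpha", "beta")
    measure: str = "envelope"
    amplitude_criterion_uv: float = 100.0
    outlier_sd: float = 5.0
    n_perm: int = 10_000
    cluster_alpha: float = 0.05
    mark_alpha: float = 0.05
    fdr_q: float = 0.05
    save_epochs: bool = False
    out_dir: str = "run_output"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if any(m > n for m, n in zip(self.eeg_missing, self.group_sizes)):
            raise ValueError("eeg_missing cannot exceed group sizes")

    def montage(self) -> Montage:
        if self.montage_path:
            return Montage.from_yaml(self.montage_path)
        return default_montage()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(dataclasses.asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, sub in (
            ("covariate_effect", CovariateEffectConfig),
            ("behavior_effect", BehaviorEffectConfig),
            ("eeg_effect", EegEffectConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**{k: _tuplify(v) for k, v in raw[key].items()})
        for key in ("group_sizes", "eeg_missing", "bands"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _tuplify(v):
    if isinstance(v, list):
        return tuple(_tuplify(x) for x in v)
    return v


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed ({context}): {cause}")
        self.stage = stage


def subject_band_scalars(
    epoch_sets: dict,
    bands: tuple[str, ...],
    measure: str = "envelope",
    amplitude_criterion_uv: float = 100.0,
    outlier_sd: float = 5.0,
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Preprocess every subject and collect per-band scalar tables.

    Returns ``{band: DataFrame}`` with subjects as rows and a (channel,
    period) MultiIndex over columns (including the parietal-cluster row), and
    the combined rejection log. Only rare-gain choice trials enter the trial
    average. Subjects whose rare-gain trials are all rejected are skipped
    with a log entry.
    """
    rows: dict[str, dict[str, dict]] = {b: {} for b in bands}
    log: list[dict] = []
    for sid in sorted(epoch_sets):
        ep = epoch_sets[sid]
        try:
            filt = pp.resample_and_filter(ep)
            clean, rej = pp.reject_trials(
                filt, amplitude_uv=amplitude_criterion_uv, z_thresh=outlier_sd
            )
        except ValueError as exc:
            log.append({"subject": sid, "event": "skipped", "reason": str(exc)})
            continue
        for entry in rej:
            log.append({"subject": sid, "event": "trial_rejected", **entry})
        rareg = (clean.metadata["choice"] == "RareG").to_numpy()
        if not rareg.any():
            log.append({"subject": sid, "event": "skipped", "reason": "no RareG trials retained"})
            continue
        n_rej = ep.n_trials - clean.n_trials
        for band in bands:
            act = pp.band_decompose_and_average(clean, band, trial_mask=rareg, n_rejected=n_rej)
            act = pp.baseline_correct(act)
            summary = pp.summarize_periods(act, measure=measure)
            rows[band][sid] = {
                (ch, per): summary.loc[ch, per]
                for ch in summary.index
                for per in summary.columns
            }
    tables = {}
    for band in bands:
        df = pd.DataFrame.from_dict(rows[band], orient="index")
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["channel", "period"])
        df.index.name = "subject_id"
        tables[band] = pp.mask_group_outliers(df, z_thresh=outlier_sd)
    return tables, log


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_cov, rng_beh, rng_eeg, rng_stats = (np.random.default_rng(s) for s in seeds)
    montage = config.montage()
    events: list[dict] = [{"event": "start", "seed": config.seed}]

    # --- cohort -----------------------------------------------------------
    try:
        covariates = generate_covariates(config.group_sizes, config.covariate_effect, rng_cov)
        behavior = generate_cohort_behavior(
            covariates, config.behavior_effect, rng_beh, n_trials=config.n_trials
        )
    except Exception as exc:
        raise StageError("synthetic_cohort", "generation", exc) from exc
    ldio.write_covariates_csv(covariates, out / "covariates.csv")
    ldio.write_behavior_csv(behavior, out / "behavior.csv")
    events.append({"event": "cohort_done", "n_subjects": len(covariates)})

    # --- behavior analysis ------------------------------------------------
    try:
        metrics = bh.compute_metrics(behavior)
        models = {
            name: bh.fit_group_model(metrics, covariates, outcome=name).to_dict()
            for name in ("win_stay_expt", "win_stay_baseline", "gain_freq_bias")
        }
    except Exception as exc:
        raise StageError("behavior_analysis", "group models", exc) from exc
    metrics.to_csv(out / "metrics.csv", index=False)
    with open(out / "behavior_models.json", "w") as fh:
        json.dump(models, fh, indent=2)
    demo = gs.demographic_comparison(covariates)
    demo.to_csv(out / "demographics.csv", index=False)
    events.append({"event": "behavior_done", "n_metrics": len(metrics)})

    # --- EEG simulation ---------------------------------------------------
    try:
        with_eeg = []
        for group, n_missing in zip(GROUPS, config.eeg_missing):
            sids = covariates.loc[covariates["group"] == group, "subject_id"].to_numpy()
            drop = set(rng_eeg.choice(sids, size=n_missing, replace=False))
            with_eeg.extend(s for s in sids if s not in drop)
        epoch_sets = simulate_epochs(
            behavior[behavior["subject_id"].isin(with_eeg)],
            covariates,
            config.eeg_effect,
            montage,
            rng_eeg,
            sfreq=config.sfreq,
        )
    except Exception as exc:
        raise StageError("synthetic_eeg", "simulation", exc) from exc
    if config.save_epochs:
        ldio.write_epochs_h5(epoch_sets, out / "epochs.h5")
    events.append({"event": "eeg_done", "n_with_eeg": len(epoch_sets)})

    # --- preprocessing ----------------------------------------------------
    try:
        tables, pp_log = subject_band_scalars(
            epoch_sets, config.bands, config.measure,
            config.amplitude_criterion_uv, config.outlier_sd,
        )
    except Exception as exc:
        raise StageError("eeg_preprocess", "band scalars", exc) from exc
    scalars_long = pd.concat(
        {band: df.stack(["channel", "period"], future_stack=True) for band, df in tables.items()},
        names=["band"],
    ).rename("value").reset_index()
    scalars_long.to_csv(out / "band_scalars.csv", index=False)
    events.extend({"stage": "eeg_preprocess", **e} for e in pp_log)

    # --- group statistics -------------------------------------------------
    contrast = gs.direct_vs_other(covariates)
    try:
        map_frames = []
        map_results = []
        for band in config.bands:
            for period in pp.PERIODS:
                chans = [c for c in montage.ch_names if (c, period) in tables[band].columns]
                scal = tables[band].loc[:, [(c, period) for c in chans]]
                scal.columns = chans
                res = gs.permutation_cluster_map(
                    scal, contrast, montage, n_perm=config.n_perm,
                    cluster_alpha=config.cluster_alpha, mark_alpha=config.mark_alpha,
                    rng=rng_stats, band=band, period=period,
                )
                map_results.append(res)
        reject, p_adj = gs.fdr_across_maps(
            [r.map_pvalue for r in map_results], q=config.fdr_q
        )
        for r, rej, pa in zip(map_results, reject, p_adj):
            r.fdr_significant = bool(rej)
            r.fdr_pvalue = float(pa)
            map_frames.append(r.to_frame())
    except Exception as exc:
        raise StageError("group_stats", "permutation maps", exc) from exc
    pd.concat(map_frames, ignore_index=True).to_csv(out / "map_stats.csv", index=False)
    maps_summary = [
        {"band": r.band, "period": r.period, "map_pvalue": r.map_pvalue,
         "fdr_pvalue": r.fdr_pvalue, "fdr_significant": r.fdr_significant,
         "n_clusters": len(r.clusters)}
        for r in map_results
    ]
    with open(out / "maps_summary.json", "w") as fh:
        json.dump(maps_summary, fh, indent=2)

    # parietal alpha cluster t-tests per period
    alpha = tables["alpha"]
    direct_ids = contrast[contrast].index
    cluster_tests = {}
    for period in pp.PERIODS:
        col = alpha[("parietal_cluster", period)]
        x = col[col.index.isin(direct_ids)].to_numpy()
        y = col[~col.index.isin(direct_ids)].to_numpy()
        cluster_tests[period] = gs.cluster_ttest(x, y)
    with open(out / "alpha_cluster_tests.json", "w") as fh:
        json.dump(cluster_tests, fh, indent=2)

    # neurobehavioral interaction models: parietal electrodes x periods
    try:
        neural_table = {
            (elec, period): alpha[(elec, period)]
            for elec in PARIETAL_CLUSTER
            for period in pp.PERIODS
        }
        family = gs.neurobehavioral_family(metrics, covariates, neural_table, q=config.fdr_q)
        cluster_models = gs.neurobehavioral_family(
            metrics, covariates,
            {("parietal_cluster", p): alpha[("parietal_cluster", p)] for p in pp.PERIODS},
            q=config.fdr_q,
        )
    except Exception as exc:
        raise StageError("group_stats", "neurobehavioral models", exc) from exc
    family.to_csv(out / "neurobehavioral_models.csv", index=False)
    cluster_models.to_csv(out / "neurobehavioral_cluster_models.csv", index=False)

    pz_choice = alpha[("Pz", "choice")]
    spearman = {
        "other": gs.within_group_spearman(
            metrics, pz_choice, covariates, ("indirectly_exposed", "non_exposed")
        ),
        "directly_exposed": gs.within_group_spearman(
            metrics, pz_choice, covariates, "directly_exposed"
        ),
    }
    with open(out / "spearman.json", "w") as fh:
        json.dump(spearman, fh, indent=2)
    events.append({"event": "stats_done", "n_maps": len(map_results)})

    # --- manifest ---------------------------------------------------------
    config.to_yaml(out / "config.yaml")
    with open(out / "log.jsonl", "w") as fh:
        for e in events:
            fh.write(json.dumps(_plain(e)) + "\n")
    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "n_subjects": len(covariates),
        "n_with_eeg": len(epoch_sets),
        "n_maps": len(map_results),
        "files": {p.name: _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
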