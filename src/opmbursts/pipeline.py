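"""End-to-end orchestration: paradigm -> simulate -> preprocess -> beamform ->
envelope -> bursts -> stats, for a cohort of synthetic subjects.

Each synthetic subject gets an independent seeded dataset; per-subject
condition summaries (cue-window and probe-window beta CNR, burst count /
amplitude / duration, burst probability) feed the across-subject Wilcoxon /
Benjamini-Hochberg contrast report.  Every random stage draws from a named
child stream of the master seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beamformer as bf
from . import bursts as bu
from . import envelope as ev
from . import hmm as hm
from . import preprocess as pp
from .config import PipelineConfig
from .paradigm import CUE_WINDOW_S, TRIAL_DURATION_S, generate_schedule
from .stats import attention_contrast_report
from .synth import (
    REGION_HANDS,
    BurstSpec,
    SyntheticDataset,
    build_helmet_array,
    make_source_model,
    simulate_recording,
)

#: hemisphere label -> (region label, hand whose stimulation drives it)
HEMISPHERES = {"left": ("left_postcentral", "right"),
               "right": ("right_postcentral", "left")}

PROBE_TEST_WINDOW_S = (0.0, 0.26)    # beta amplitude during probe delivery


@dataclass
class SubjectResult:
    subject: int
    envelope_rows: list[dict]
    burst_rows: list[dict]
    cnr_timecourses: dict = field(default_factory=dict)   # (hemi, cond) -> CNRCondition
    burst_prob: dict = field(default_factory=dict)        # (hemi, cond) -> BurstProbability
    qc: dict = field(default_factory=dict)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    subject_seeds: list[int]
    stages: list[str]
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    subjects: list[SubjectResult]
    manifest: RunManifest
    envelope_df: pd.DataFrame = None
    burst_df: pd.DataFrame = None


def _burst_spec(cfg: PipelineConfig) -> BurstSpec:
    b = cfg.simulation.burst
    return BurstSpec(
        baseline_rate=b.baseline_rate,
        duration_law=(b.duration_mu, b.duration_sigma),
        amplitude=b.amplitude,
        carrier=(b.alpha_weight, b.beta_weight),
        attended_rate_factor=b.attended_rate_factor,
        stim_suppression_factor=b.stim_suppression_factor,
    )


def simulate_subject(cfg: PipelineConfig, rng: np.random.Generator) -> SyntheticDataset:
    schedule = generate_schedule(
        cfg.paradigm.n_trials, cfg.paradigm.rest_every, rng,
        response_error_rate=cfg.paradigm.response_error_rate,
        gamma_shape=cfg.paradigm.gamma_shape, gamma_scale=cfg.paradigm.gamma_scale,
    )
    array = build_helmet_array(cfg.simulation.n_sensors, cfg.simulation.helmet_radius, rng)
    model = make_source_model(cfg.simulation.n_regions)
    return simulate_recording(
        schedule, model, array, _burst_spec(cfg),
        noise_sd=cfg.simulation.noise_sd,
        drift_amplitude=cfg.simulation.drift_amplitude,
        fs=cfg.simulation.fs, rng=rng,
    )


def preprocess_subject(cfg: PipelineConfig, dataset: SyntheticDataset):
    """QC + HFC; returns (corrected recording, trial labels, kept mask, qc dict)."""
    rec = dataset.recording
    qc_rec = rec
    if cfg.preprocess.qc_duration_s is not None:
        n_qc = int(round(cfg.preprocess.qc_duration_s * rec.fs))
        if n_qc < rec.n_samples:
            qc_rec = rec.copy_with(data=rec.data[:, :n_qc])
    psd = pp.welch_psd(qc_rec, segment_s=cfg.preprocess.welch_segment_s)
    bad = pp.detect_bad_channels(psd, floor_limit=cfg.preprocess.floor_fT,
                                 band=cfg.preprocess.band)
    rec = pp.mark_bad_channels(rec, bad)
    rec, _ = pp.homogeneous_field_correction(rec)
    trials = pp.segment_trials(rec)
    trials = pp.reject_bad_trials(trials, k=cfg.preprocess.sd_k,
                                  good_channels=rec.good)
    qc = dict(n_bad_channels=len(bad),
              n_rejected_trials=int((~trials.kept).sum()))
    return rec, trials.labels, trials.kept, qc


def _kept_sample_mask(labels: pd.DataFrame, kept: np.ndarray, fs: float,
                      n_samples: int) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    n_per = int(round(TRIAL_DURATION_S * fs))
    for start in labels.start_s[kept]:
        i0 = int(round(start * fs))
        mask[i0:i0 + n_per] = True
    return mask


def _aligned_to_grid(series: np.ndarray, fs: float, emb: hm.EmbeddedSeries,
                     n_full: int) -> np.ndarray:
    """Resample a continuous series to the embedded grid, full length (padded)."""
    ds, fs_ds = hm.downsample(series, fs, emb.fs)
    return ds[:n_full]


def analyse_hemisphere(cfg: PipelineConfig, hemi: str, ve_beta, ve_broad,
                       labels: pd.DataFrame, kept: np.ndarray,
                       events: pd.DataFrame, rng: np.random.Generator):
    """Envelope-CNR and burst analyses for one sensorimotor region."""
    region, hand = HEMISPHERES[hemi]
    ridx = ve_beta.labels.index(region)
    fs = ve_beta.fs
    attended_cue = f"cue_{hand}"     # attention on this region's hand
    nonattended_cue = "cue_left" if attended_cue == "cue_right" else "cue_right"

    # --- beta envelope CNR -------------------------------------------------
    env = ev.hilbert_envelope(ve_beta.data[ridx], fs, region=region, band="beta")
    baseline = ev.baseline_stats(env, labels, kept)
    cnr_tc = ev.cnr(env, baseline)

    cnr_cond = {c: ev.average_trials(cnr_tc, fs, labels, c, kept)
                for c in ("cue_left", "cue_right")}
    env_rows = [dict(
        hemisphere=hemi, window="cue",
        attended=ev.window_average(cnr_cond[attended_cue].mean, fs, CUE_WINDOW_S),
        nonattended=ev.window_average(cnr_cond[nonattended_cue].mean, fs, CUE_WINDOW_S),
    )]

    kept_idx = set(labels.trial_index[kept].astype(int))
    epochs = ev.epoch_probes(cnr_tc, fs, events, kept_trials=kept_idx)
    pair = {"attended": epochs[f"attend_{hand}_stim_{hand}"],
            "nonattended": epochs[f"attend_{nonattended_cue.removeprefix('cue_')}_stim_{hand}"]}
    pair = ev.equalise_trial_counts(pair, rng)
    t0 = ev.PROBE_EPOCH_WINDOW_S[0]
    env_rows.append(dict(
        hemisphere=hemi, window="probe",
        attended=ev.window_average(pair["attended"].mean(axis=0), fs,
                                   PROBE_TEST_WINDOW_S, t0=t0),
        nonattended=ev.window_average(pair["nonattended"].mean(axis=0), fs,
                                      PROBE_TEST_WINDOW_S, t0=t0),
    ))

    # --- TDE-HMM bursts on the broadband virtual electrode ----------------
    tde = hm.TDEConfig(n_lags=cfg.hmm.n_lags, target_fs=cfg.hmm.target_fs,
                       pca_dims=cfg.hmm.pca_dims)
    x = ve_broad.data[ridx]
    emb = hm.embed(x, fs, tde)
    model = hm.fit_hmm(emb.X, K=cfg.hmm.k, n_restarts=cfg.hmm.n_restarts,
                       tol=cfg.hmm.tol, max_iter=cfg.hmm.max_iter, rng=rng)
    post = hm.forward_backward(model, emb.X)
    binary = bu.binarise(post.gamma, cfg.hmm.threshold)

    fs_ds = emb.fs
    n_full = int(round(len(x) / fs * fs_ds))
    h = (cfg.hmm.n_lags - 1) // 2
    # full-length series on the downsampled grid, embedding edges zero-padded
    beta_env_ds = _aligned_to_grid(env.samples, fs, emb, n_full)
    broad_ds, _ = hm.downsample(x, fs, fs_ds)
    broad_env_ds = ev.hilbert_envelope(broad_ds[:n_full], fs_ds).samples

    state = bu.select_burst_state(binary, beta_env_ds[h:h + binary.shape[0]])
    full_binary = np.zeros(n_full, dtype=bool)
    full_binary[h:h + binary.shape[0]] = binary[:, state]
    events_all = bu.burst_events(full_binary, fs_ds, broad_env_ds)

    # trial-relative burst probability per cue condition
    n_per = int(round(TRIAL_DURATION_S * fs_ds))
    bp = {}
    burst_rows = []
    for cond_name, cue in (("attended", attended_cue), ("nonattended", nonattended_cue)):
        sel = labels[np.asarray(kept) & (~labels.is_rest).to_numpy()
                     & (labels.cue == cue.removeprefix("cue_")).to_numpy()]
        seg = np.stack([
            full_binary[int(round(s * fs_ds)): int(round(s * fs_ds)) + n_per]
            for s in sel.start_s
        ])
        bp[cond_name] = bu.burst_probability(seg, fs_ds)

        # burst metrics in cue windows (trial clock) and probe windows
        cue_windows = [(s + bu.CUE_BURST_WINDOW_S[0], s + bu.CUE_BURST_WINDOW_S[1])
                       for s in sel.start_s]
        probes = events[(events.trial_type.str.startswith("probe_"))
                        & (events.hand == hand)
                        & (~events.is_target) & (~events.bad_response)
                        & (events.trial_index.isin(sel.trial_index))]
        probe_windows = [(o + bu.PROBE_BURST_WINDOW_S[0], o + bu.PROBE_BURST_WINDOW_S[1])
                         for o in probes.onset]
        for win_name, windows in (("cue", cue_windows), ("probe", probe_windows)):
            in_win = [e for w in windows for e in events_all
                      if e.onset_s >= w[0] and e.offset_s < w[1]]
            n_win = max(len(windows), 1)
            burst_rows.append(dict(
                hemisphere=hemi, window=win_name, condition=cond_name,
                count=len(in_win) / n_win,
                amplitude=float(np.mean([e.peak_amplitude for e in in_win]))
                if in_win else np.nan,
                duration=float(np.mean([e.duration_s for e in in_win]))
                if in_win else np.nan,
            ))
    return env_rows, burst_rows, cnr_cond, bp


def run_subject(cfg: PipelineConfig, subject: int,
                rng: np.random.Generator) -> SubjectResult:
    dataset = simulate_subject(cfg, rng)
    rec, labels, kept, qc = preprocess_subject(cfg, dataset)
    mask = _kept_sample_mask(labels, kept, rec.fs, rec.n_samples)
    ve_broad = bf.reconstruct_virtual_electrodes(
        rec, dataset.source_model, dataset.array, cfg.beamformer.broadband, mask)
    ve_beta = bf.reconstruct_virtual_electrodes(
        rec, dataset.source_model, dataset.array, cfg.beamformer.beta_band, mask)

    env_rows, burst_rows = [], []
    cnr_tcs, bps = {}, {}
    for hemi in HEMISPHERES:
        e_rows, b_rows, cnr_cond, bp = analyse_hemisphere(
            cfg, hemi, ve_beta, ve_broad, labels, kept, rec.events, rng)
        for r in e_rows:
            r["subject"] = subject
        for r in b_rows:
            r["subject"] = subject
        env_rows += e_rows
        burst_rows += b_rows
        for cond, c in cnr_cond.items():
            cnr_tcs[(hemi, cond)] = c
        for cond, p in bp.items():
            bps[(hemi, cond)] = p
    return SubjectResult(subject=subject, envelope_rows=env_rows,
                         burst_rows=burst_rows, cnr_timecourses=cnr_tcs,
                         burst_prob=bps, qc=qc)


def _burst_rows_to_contrast(burst_rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(burst_rows)
    out = []
    for (subj, hemi, window), grp in df.groupby(["subject", "hemisphere", "window"]):
        att = grp[grp.condition == "attended"].iloc[0]
        non = grp[grp.condition == "nonattended"].iloc[0]
        for metric in ("count", "amplitude", "duration"):
            out.append(dict(subject=subj, hemisphere=hemi, window=window,
                            metric=metric, attended=att[metric],
                            nonattended=non[metric]))
    return pd.DataFrame(out)


def attention_effect_study(n_runs: int = 20, seed: int = 0, effect: bool = True,
                           cfg: PipelineConfig | None = None) -> dict:
    """Repeated seeded cohort runs summarising the attention contrast.

    For each run: the group-mean attended-minus-nonattended cue-window beta
    CNR and burst-probability contrasts (negative = suppression with
    attention), and whether any BH-corrected test rejected.  ``effect=False``
    switches the generator's attended rate factor to 1 (no injected effect),
    giving the null-calibration arm.
    """
    cfg = PipelineConfig() if cfg is None else cfg
    if not effect:
        sim = cfg.simulation.model_copy(
            update={"burst": cfg.simulation.burst.model_copy(
                update={"attended_rate_factor": 1.0})})
        cfg = cfg.model_copy(update={"simulation": sim})
    ss = np.random.SeedSequence((seed, 1 if effect else 2))
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_runs)]

    cnr_contrasts, bp_contrasts, any_rejection = [], [], []
    for run_seed in run_seeds:
        res = run_pipeline(cfg, seed=run_seed)
        cue = res.envelope_df[res.envelope_df.window == "cue"]
        cnr_contrasts.append(float((cue.attended - cue.nonattended).mean()))
        deltas = []
        for sub in res.subjects:
            for hemi in HEMISPHERES:
                att = sub.burst_prob[(hemi, "attended")]
                non = sub.burst_prob[(hemi, "nonattended")]
                w = (att.times >= CUE_WINDOW_S[0]) & (att.times < CUE_WINDOW_S[1])
                deltas.append(att.prob[w].mean() - non.prob[w].mean())
        bp_contrasts.append(float(np.mean(deltas)))
        any_rejection.append(bool(res.report.bh_rejected.any()))
    return dict(run_seeds=run_seeds, cnr_contrasts=cnr_contrasts,
                bp_contrasts=bp_contrasts, any_rejection=any_rejection)


def run_pipeline(cfg: PipelineConfig | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run the full multi-subject analysis; returns the contrast report."""
    cfg = PipelineConfig() if cfg is None else cfg
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in ss.spawn(cfg.n_subjects)]

    caught: list[str] = []
    subjects = []
    for i, sub_seed in enumerate(subject_seeds):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            subjects.append(run_subject(cfg, i, np.random.default_rng(sub_seed)))
            caught += [f"sub-{i:02d}: {x.message}" for x in w]

    envelope_df = pd.DataFrame([r for s in subjects for r in s.envelope_rows])
    burst_df = _burst_rows_to_contrast([r for s in subjects for r in s.burst_rows])
    report = attention_contrast_report(envelope_df, burst_df, q=cfg.stats.q,
                                       merge_families=cfg.stats.merge_families)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(
        config_hash=cfg_hash, seed=master, subject_seeds=subject_seeds,
        stages=["paradigm", "simulate", "preprocess", "beamform", "envelope",
                "bursts", "stats"],
        warnings=caught,
    )
    return PipelineResult(report=report, subjects=subjects, manifest=manifest,
                          envelope_df=envelope_df, burst_df=burst_df)
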