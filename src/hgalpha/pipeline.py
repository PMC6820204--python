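"""End-to-end orchestration: simulate -> preprocess -> localize -> analyze -> test.

A run produces, per hemisphere: a functional localization of gyrus contacts,
stimulus- and offset-locked band power per region and condition, aperiodic
slope / narrowband alpha decompositions, and per-contact distance maps; at
the group level (N = hemispheres) the battery of exact signed-rank tests the
study design calls for, plus per-hemisphere trial-label permutation tests
with FDR correction. Every random draw descends from the single run seed and
region labels used by statistics always come from the localization stage,
never from simulator ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import localize as loc
from . import phaselock, preprocess, spectral, stats, timefreq
from .containers import ContactSet, EpochedRecording
from .simulate import SimulatedDataset, SimulationParams, simulate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_full_analysis"]

REGIONS = ("pmHG", "alHG")
CONDITIONS = ("clear", "vocoded")


@dataclass(frozen=True)
class RunConfig:
    """All analysis constants of a pipeline run."""

    sim: SimulationParams = field(default_factory=SimulationParams)
    wavelet: timefreq.WaveletConfig = field(default_factory=timefreq.WaveletConfig)
    localization: loc.LocalizationConfig = field(default_factory=loc.LocalizationConfig)
    alpha_band: tuple[float, float] = (7.0, 10.0)
    hg_band: tuple[float, float] = (70.0, 150.0)
    stim_window: tuple[float, float] = (0.5, 1.2)
    prestim_window: tuple[float, float] = (-0.6, -0.1)
    offset_window: tuple[float, float] = (-1.2, -0.5)
    offset_baseline: tuple[float, float] = (0.1, 0.6)
    target_rate: float = 1000.0
    line_freq: float = 60.0
    n_perm: int = 1000
    q: float = 0.05
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, sim=replace(self.sim, seed=seed))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Tables produced by one full run."""

    localization: pd.DataFrame      # per contact
    region_power: pd.DataFrame      # hemisphere x region x measure (x condition)
    tests: pd.DataFrame             # tidy group-level test results
    permutation: pd.DataFrame       # per-hemisphere permutation p-values + FDR
    distance_decay: pd.DataFrame    # per-hemisphere slopes
    distance_decay_test: stats.TestResult
    contact_map: pd.DataFrame       # per contact: distance, alpha_dB, hg_dB
    spectral_table: pd.DataFrame    # hemisphere x region x window: slope, alpha
    config: RunConfig
    log: dict

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.localization.to_csv(out / "localization.csv", index=False)
        self.region_power.to_csv(out / "region_power.csv", index=False)
        self.tests.to_csv(out / "tests.csv", index=False)
        self.permutation.to_csv(out / "permutation.csv", index=False)
        self.distance_decay.to_csv(out / "distance_decay.csv", index=False)
        self.contact_map.to_csv(out / "contact_map.csv", index=False)
        self.spectral_table.to_csv(out / "spectral.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=2)


def _preprocess_epochs(rec: EpochedRecording, config: RunConfig
                       ) -> EpochedRecording:
    """Line-noise removal and downsampling of an epoched recording."""
    clean = preprocess.remove_line_noise(rec.data, rec.sample_rate,
                                         config.line_freq)
    data, rate = preprocess.resample(clean, rec.sample_rate, config.target_rate)
    times = rec.times[0] + np.arange(data.shape[-1]) / rate
    return EpochedRecording(data, rate, times, rec.conditions, rec.contact_ids,
                            sentence_durations=rec.sentence_durations)


def _localize_hemisphere(clicks: EpochedRecording, contacts: ContactSet,
                         config: RunConfig, seed: int) -> pd.DataFrame:
    rate = config.localization.itpc_rate
    at_rate = clicks.select_trials(clicks.conditions.astype(float) == rate)
    itpc = phaselock.compute_itpc(at_rate)
    chance = phaselock.surrogate_chance_level(at_rate, seed=seed)
    evoked, times = loc.averaged_evoked_potential(clicks)
    report = loc.classify_contacts(itpc, chance, evoked, times,
                                   contacts.on_heschl, config.localization)
    # per-rate ITPC at the stimulus-rate bin, for the localization report
    for r in np.unique(clicks.conditions.astype(float)):
        sub = clicks.select_trials(clicks.conditions.astype(float) == r)
        res = phaselock.compute_itpc(sub)
        report[f"itpc_{r:g}Hz"] = phaselock.itpc_at_stimulus_rate(res, r)
    report.insert(1, "hemisphere_id", contacts.hemisphere_id)
    return report


def _trial_alpha_db(sentence: EpochedRecording, config: RunConfig
                    ) -> np.ndarray:
    """Per-trial, per-contact alpha power in dB re. the same trial's baseline."""
    low = config.wavelet.low_freqs()
    band = config.alpha_band
    freqs = low[(low >= band[0] - 1e-9) & (low <= band[1] + 1e-9)]
    tf = timefreq.morlet_power(sentence, config.wavelet, freqs=freqs,
                               keep_trials=True)
    win = timefreq.band_window_power(tf, band, config.stim_window)
    base = timefreq.band_window_power(tf, band, config.wavelet.baseline_window)
    return 10.0 * np.log10(win / base)


def run_full_analysis(config: RunConfig | None = None,
                      dataset: SimulatedDataset | None = None
                      ) -> PipelineResult:
    """Run the complete analysis on a (by default freshly simulated) dataset."""
    if config is None:
        config = RunConfig()
    if dataset is None:
        dataset = simulate_dataset(replace(config.sim, seed=config.seed))
    n_hemi = dataset.params.n_hemispheres
    seed_seq = np.random.SeedSequence([config.seed, 0xA1FA]).generate_state(
        2 * n_hemi + 1)

    loc_frames = []
    region_rows = []
    spectral_rows = []
    perm_rows = []
    contact_rows = []
    # per-hemisphere group-level scalars
    g = {key: np.full(n_hemi, np.nan) for key in [
        "alpha_db_pmHG", "alpha_db_alHG", "hg_db_pmHG", "hg_db_alHG",
        "offset_db_pmHG", "offset_db_alHG",
        "raw_pre_pmHG", "raw_pre_alHG", "raw_post_pmHG", "raw_post_alHG"]}
    cond_alpha = np.full((n_hemi, 2, 2), np.nan)   # region x condition
    slope_cells = np.full((n_hemi, 2, 2), np.nan)  # region x window (pre, post)
    alpha_cells = np.full((n_hemi, 2, 2), np.nan)  # whitened narrowband

    for h in range(n_hemi):
        contacts = dataset.hemisphere_contacts(h)
        clicks = _preprocess_epochs(dataset.click_epochs[h], config)
        sentence = _preprocess_epochs(dataset.sentence_epochs[h], config)

        report = _localize_hemisphere(clicks, contacts, config,
                                      int(seed_seq[2 * h]))
        loc_frames.append(report)
        assigned = report["assigned_field"].to_numpy()
        region_masks = {r: assigned == r for r in REGIONS}
        if not all(m.any() for m in region_masks.values()):
            raise RuntimeError(f"hemisphere {h}: a region has no contacts "
                               "after localization")

        # --- stimulus-locked time-frequency power, per condition -----------
        low, high = config.wavelet.low_freqs(), config.wavelet.high_freqs()
        cond_raw = {}
        for cond in CONDITIONS:
            sub = sentence.select_trials(sentence.conditions == cond)
            tf_low = timefreq.morlet_power(sub, config.wavelet, freqs=low)
            tf_high = timefreq.morlet_power(sub, config.wavelet, freqs=high)
            cond_raw[cond] = timefreq.TFPower(
                np.concatenate([tf_low.power, tf_high.power], axis=1),
                np.concatenate([low, high]), tf_low.times, tf_low.contact_ids,
                "raw")
        overall_raw = timefreq.TFPower(
            0.5 * (cond_raw["clear"].power + cond_raw["vocoded"].power),
            cond_raw["clear"].frequencies, cond_raw["clear"].times,
            cond_raw["clear"].contact_ids, "raw")
        overall_db = timefreq.baseline_db(overall_raw,
                                          config.wavelet.baseline_window)

        alpha_db = timefreq.band_window_power(overall_db, config.alpha_band,
                                              config.stim_window)
        hg_db = timefreq.band_window_power(overall_db, config.hg_band,
                                           config.stim_window)
        raw_pre = timefreq.band_window_power(overall_raw, config.alpha_band,
                                             config.prestim_window)
        raw_post = timefreq.band_window_power(overall_raw, config.alpha_band,
                                              config.stim_window)
        offset_db = timefreq.offset_locked_power(
            sentence, config.wavelet, config.alpha_band,
            config.offset_window, config.offset_baseline)

        for r in REGIONS:
            m = region_masks[r]
            g[f"alpha_db_{r}"][h] = alpha_db[m].mean()
            g[f"hg_db_{r}"][h] = hg_db[m].mean()
            g[f"offset_db_{r}"][h] = offset_db[m].mean()
            g[f"raw_pre_{r}"][h] = raw_pre[m].mean()
            g[f"raw_post_{r}"][h] = raw_post[m].mean()

        for ci, cond in enumerate(CONDITIONS):
            db = timefreq.baseline_db(cond_raw[cond],
                                      config.wavelet.baseline_window)
            a = timefreq.band_window_power(db, config.alpha_band,
                                           config.stim_window)
            for ri, r in enumerate(REGIONS):
                cond_alpha[h, ri, ci] = a[region_masks[r]].mean()
                region_rows.append({
                    "hemisphere_id": h, "region": r, "condition": cond,
                    "alpha_db": a[region_masks[r]].mean()})

        # --- per-trial alpha for hemisphere-level permutation tests ---------
        trial_db = _trial_alpha_db(sentence, config)  # (trials, contacts)
        pm_trials = trial_db[:, region_masks["pmHG"]].mean(axis=1)
        al_trials = trial_db[:, region_masks["alHG"]].mean(axis=1)
        clear_mask = sentence.conditions == "clear"
        p_region = stats.trial_label_permutation(
            pm_trials, al_trials, config.n_perm, int(seed_seq[2 * h + 1]))
        p_cond = stats.trial_label_permutation(
            al_trials[clear_mask], al_trials[~clear_mask], config.n_perm,
            int(seed_seq[2 * h + 1]) + 1)
        perm_rows.append({"hemisphere_id": h,
                          "p_region_contrast": p_region,
                          "p_clear_vs_vocoded_alHG": p_cond})

        # --- spectral decomposition (region-mean spectra, pre vs post) ------
        for wi, window in enumerate((config.prestim_window, config.stim_window)):
            freqs_s, spectra = spectral.window_spectrum(sentence, window)
            for ri, r in enumerate(REGIONS):
                dec = spectral.decompose(freqs_s,
                                         spectra[region_masks[r]].mean(axis=0),
                                         band=config.alpha_band)
                slope_cells[h, ri, wi] = dec.slope
                alpha_cells[h, ri, wi] = dec.alpha_narrowband_power
                spectral_rows.append({
                    "hemisphere_id": h, "region": r,
                    "window": "prestimulus" if wi == 0 else "poststimulus",
                    "slope": dec.slope,
                    "narrowband_alpha": dec.alpha_narrowband_power})

        # --- per-contact distance map (localized alHG centroid) -------------
        dist = contacts.distances_to_centroid(region_masks["alHG"])
        for c in range(len(contacts)):
            contact_rows.append({
                "contact_id": contacts.contact_id[c], "hemisphere_id": h,
                "assigned_field": assigned[c],
                "distance_mm": dist[c], "alpha_db": alpha_db[c],
                "hg_db": hg_db[c]})

    # ---------------- group-level inference ---------------------------------
    contact_map = pd.DataFrame(contact_rows)
    fits, decay_test = stats.distance_decay_fit(
        contact_map["distance_mm"].to_numpy(),
        contact_map["hemisphere_id"].to_numpy(),
        contact_map["alpha_db"].to_numpy())

    def row(name, result):
        return result.as_row(name)

    tests = [
        row("alpha_db_alHG_vs_pmHG",
            stats.exact_signed_rank(g["alpha_db_alHG"], g["alpha_db_pmHG"])),
        row("hg_db_pmHG_vs_alHG",
            stats.exact_signed_rank(g["hg_db_pmHG"], g["hg_db_alHG"])),
        row("offset_alpha_alHG_vs_pmHG",
            stats.exact_signed_rank(g["offset_db_alHG"], g["offset_db_pmHG"])),
        row("clear_vs_vocoded_alHG",
            stats.exact_signed_rank(cond_alpha[:, 1, 0], cond_alpha[:, 1, 1])),
        row("clear_vs_vocoded_pmHG",
            stats.exact_signed_rank(cond_alpha[:, 0, 0], cond_alpha[:, 0, 1])),
        row("stimulus_by_region_interaction",
            stats.interaction_contrast(cond_alpha)),
        row("raw_alpha_prestim_alHG_vs_pmHG",
            stats.exact_signed_rank(g["raw_pre_alHG"], g["raw_pre_pmHG"])),
        row("raw_alpha_poststim_alHG_vs_pmHG",
            stats.exact_signed_rank(g["raw_post_alHG"], g["raw_post_pmHG"])),
        row("slope_pre_vs_post_alHG",
            stats.exact_signed_rank(slope_cells[:, 1, 0], slope_cells[:, 1, 1])),
        row("slope_pre_vs_post_pmHG",
            stats.exact_signed_rank(slope_cells[:, 0, 0], slope_cells[:, 0, 1])),
        row("slope_interaction", stats.interaction_contrast(slope_cells)),
        row("whitened_alpha_pre_vs_post_alHG",
            stats.exact_signed_rank(alpha_cells[:, 1, 0], alpha_cells[:, 1, 1])),
        row("whitened_alpha_pre_vs_post_pmHG",
            stats.exact_signed_rank(alpha_cells[:, 0, 0], alpha_cells[:, 0, 1])),
        row("whitened_alpha_interaction",
            stats.interaction_contrast(alpha_cells)),
        row("distance_decay_slopes_vs_zero", decay_test),
    ]
    tests_df = pd.DataFrame(tests)
    tests_df["significant_q"] = stats.fdr_correct(
        tests_df["p"].to_numpy(), config.q)

    perm_df = pd.DataFrame(perm_rows)
    for col in ("p_region_contrast", "p_clear_vs_vocoded_alHG"):
        perm_df[col + "_fdr"] = stats.fdr_correct(perm_df[col].to_numpy(),
                                                  config.q)

    power_long = pd.DataFrame(region_rows)
    overall_rows = []
    for h in range(n_hemi):
        for r in REGIONS:
            overall_rows.append({
                "hemisphere_id": h, "region": r, "condition": "all",
                "alpha_db": g[f"alpha_db_{r}"][h],
                "hg_db": g[f"hg_db_{r}"][h],
                "offset_alpha_db": g[f"offset_db_{r}"][h],
                "raw_alpha_prestim": g[f"raw_pre_{r}"][h],
                "raw_alpha_poststim": g[f"raw_post_{r}"][h]})
    region_power = pd.concat([pd.DataFrame(overall_rows), power_long],
                             ignore_index=True)

    log = {"seed": config.seed, "config_hash": config.config_hash(),
           "n_hemispheres": n_hemi,
           "n_contacts": int(len(dataset.contacts))}
    return PipelineResult(
        localization=pd.concat(loc_frames, ignore_index=True),
        region_power=region_power,
        tests=tests_df,
        permutation=perm_df,
        distance_decay=pd.DataFrame(fits),
        distance_decay_test=decay_test,
        contact_map=contact_map,
        spectral_table=pd.DataFrame(spectral_rows),
        config=config,
        log=log,
    )
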