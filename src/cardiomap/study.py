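"""Configuration-driven paired study: simulate, analyze, compare.

A study emulates the paired ex-vivo protocol: every synthetic heart is
examined at baseline and again under a parametric drug effect that
prolongs APD/refractoriness (``drug_apd_factor`` > 1 on the recovery
time constant) and accelerates calcium reuptake (``drug_ca_factor`` <
1).  Per heart and condition the pipeline measures

* APD80 and CaTD80 at a fixed pacing cycle length, from reaction-
  diffusion movies through preprocessing, quality masking and the
  feature extractor (mean over >= 25 non-infarcted sites);
* calcium decay tau from the final paced beat's diastolic decay;
* the effective refractory period from a premature-stimulus scan;
* the alternans-threshold cycle length from a decremental burst scan
  on the heart's restitution surrogate;
* VT/VF inducibility: a premature beat on the heart's CV-restitution
  cable that blocks mid-cable on a spatially discordant substrate
  initiates reentry, rendered into a post-stimulus rapid-beat run and
  classified on the pseudo-ECG;
* the spontaneous premature-ventricular-beat burden from a rendered
  ambient recording with Poisson ectopy.

Continuous endpoints are compared with the paired t-test, inducibility
with Fisher's exact test, and everything is assembled into a
deterministic report.
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

from . import io as cio
from .alternans import cable_movie_provider, find_alternans_threshold
from .features import aggregate_sites, beat_feature_table, fit_ca_decay
from .geometry import TissueGeometry, with_scar
from .model import CellModelParams, PacingProtocol, measure_true_erp, simulate_tissue
from .preprocess import build_quality_mask, preprocess
from .restitution import RestitutionMap, run_restitution_cable
from .rhythm import assess_inducibility, compute_pvb_burden, detect_ecg_beats
from .stats import (ContingencyTable2x2, PairedSample, fisher_exact, paired_t_test,
                    report_to_text, summarize)
from .synth import ecg_from_beats


@dataclass
class StudyConfig:
    """All study knobs; defaults emulate the emulated study's conditions.

    Geometry/model defaults give a ~123 ms baseline APD80 at a 300 ms
    pacing cycle length, a drug APD increase near +8%, calcium decay tau
    near 50 ms accelerated ~5% by the drug, alternans-threshold cycle
    lengths near 127 ms (baseline) and 115 ms (drug), a baseline PVB
    burden near 0.55/min falling to near 0.12/min, and baseline
    inducibility near 10 of 14 hearts falling to near 2 of 14.
    """

    n_hearts: int = 14
    seed: int = 0
    conditions: tuple = ("baseline", "drug")

    # geometry
    grid_height: int = 50
    grid_width: int = 50
    pixel_pitch: float = 0.25
    scar_radius_px: float = 9.0
    scar_center: tuple = (25.0, 16.0)
    border_width_mm: float = 1.25

    # cell model and drug effect
    tau_close_mean: float = 70.0
    tau_close_sd: float = 6.0
    tau_ca_mean: float = 50.3
    tau_ca_sd: float = 4.8
    drug_apd_factor: float = 1.107
    drug_ca_factor: float = 0.95

    # paced acquisition
    apd_pcl: float = 300.0
    warmup_beats: int = 4
    record_beats: int = 8
    noise_snr_db: float = 20.0
    site_stride: int = 3
    # band-power SNR threshold: the scar reads ~ -6 dB and tissue >= ~7 dB
    # on unfiltered movies, so 3 dB separates them with wide margin on both
    # channels (the slower calcium waveform reads lower than voltage)
    snr_threshold_db: float = 3.0

    # ERP scan (run on a conduction strip for speed)
    erp_s1s1: float = 300.0
    erp_s1_count: int = 4
    erp_scan_start: float = 200.0
    erp_scan_step: float = 2.0
    erp_stim_amplitude: float = 1.6
    erp_strip: tuple = (16, 40)

    # restitution surrogate (alternans threshold, inducibility)
    rest_apd_max_baseline: float = 118.0
    rest_amplitude_baseline: float = 114.9
    rest_tau_baseline: float = 40.0
    rest_apd_max_drug: float = 129.0
    rest_amplitude_drug: float = 118.0
    rest_tau_drug: float = 60.0
    rest_apd_max_sd: float = 6.0
    rest_tau_sd: float = 9.0
    cv_amplitude_mean: float = 0.115
    cv_amplitude_sd: float = 0.05
    cv_tau: float = 100.0
    site_apd_sd: float = 5.0
    n_alternans_sites: int = 40
    induction_challenge_delta: float = 4.0
    pcl_start: float = 300.0
    pcl_step: float = 10.0
    pcl_min: float = 80.0

    # ectopy / PVB observation
    pvb_rate_baseline: float = 0.55
    pvb_rate_sd_baseline: float = 0.74
    pvb_drug_effect: float = 0.22  # multiplicative rate reduction
    pvb_observe_min: float = 10.0
    sinus_cycle_ms: float = 350.0

    # episode synthesis
    vt_cycle_ms: float = 130.0
    vt_beats: int = 12
    vf_probability: float = 0.1

    output_dir: str | None = None

    def geometry(self) -> TissueGeometry:
        return with_scar(self.grid_height, self.grid_width, self.pixel_pitch,
                         self.scar_center, self.scar_radius_px, self.border_width_mm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("conditions", "scar_center", "erp_strip"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["scar_center"] = list(self.scar_center)
        d["erp_strip"] = list(self.erp_strip)
        return d


# ---------------------------------------------------------------------------
# per-heart parameter draws


@dataclass
class HeartParams:
    heart_id: str
    cell: dict            # condition -> CellModelParams
    restitution: dict     # condition -> RestitutionMap
    pvb_rate: dict        # condition -> events/min
    site_apd_shift: np.ndarray
    seed: int


def draw_hearts(config: StudyConfig) -> list[HeartParams]:
    """Per-heart physiology draws; paired across conditions by design."""
    rng = np.random.default_rng(config.seed)
    hearts = []
    for i in range(config.n_hearts):
        heart_seed = int(rng.integers(0, 2**31 - 1))
        hrng = np.random.default_rng(heart_seed)
        tau_close = float(np.clip(hrng.normal(config.tau_close_mean, config.tau_close_sd),
                                  40.0, 120.0))
        tau_ca = float(np.clip(hrng.normal(config.tau_ca_mean, config.tau_ca_sd), 25.0, 90.0))
        base_cell = CellModelParams(tau_close=tau_close, tau_ca_decay=tau_ca)
        cell = {
            "baseline": base_cell,
            # "delayed" = the same heart re-examined later with no
            # intervention (the repeat-session control): identical
            # physiology, fresh measurement noise via the condition seed
            "delayed": base_cell,
            "drug": CellModelParams(tau_close=tau_close, tau_ca_decay=tau_ca,
                                    drug_apd_factor=config.drug_apd_factor,
                                    drug_ca_factor=config.drug_ca_factor),
        }
        apd_shift = float(hrng.normal(0.0, config.rest_apd_max_sd))
        tau_r_shift = float(hrng.normal(0.0, config.rest_tau_sd))
        cv_amp = float(np.clip(hrng.normal(config.cv_amplitude_mean, config.cv_amplitude_sd),
                               0.02, 0.6))
        # shift apd_max and amplitude together so their gap (and hence the
        # validity of the map) is preserved across hearts
        restitution = {
            "baseline": RestitutionMap(
                apd_max=config.rest_apd_max_baseline + apd_shift,
                amplitude_a=config.rest_amplitude_baseline + apd_shift,
                tau_restitution=max(18.0, config.rest_tau_baseline + tau_r_shift),
                cv_amplitude=cv_amp, cv_tau=config.cv_tau),
            "drug": RestitutionMap(
                apd_max=config.rest_apd_max_drug + apd_shift,
                amplitude_a=config.rest_amplitude_drug + apd_shift,
                tau_restitution=max(18.0, config.rest_tau_drug + tau_r_shift),
                cv_amplitude=cv_amp, cv_tau=config.cv_tau),
        }
        restitution["delayed"] = restitution["baseline"]
        # gamma-distributed baseline rate reproduces the skewed burden
        shape = (config.pvb_rate_baseline / config.pvb_rate_sd_baseline) ** 2
        scale = config.pvb_rate_sd_baseline**2 / config.pvb_rate_baseline
        rate_base = float(hrng.gamma(shape, scale))
        rate_drug = rate_base * config.pvb_drug_effect * float(hrng.uniform(0.7, 1.3))
        hearts.append(HeartParams(
            heart_id=f"H{i+1:02d}",
            cell=cell,
            restitution=restitution,
            pvb_rate={"baseline": rate_base, "delayed": rate_base,
                      "drug": rate_drug},
            site_apd_shift=hrng.normal(0.0, config.site_apd_sd,
                                       config.n_alternans_sites),
            seed=heart_seed,
        ))
    return hearts


# ---------------------------------------------------------------------------
# per-heart, per-condition measurements


def measure_paced_features(geometry: TissueGeometry, cell: CellModelParams,
                           config: StudyConfig, seed: int) -> dict:
    """APD80/CaTD80/tau from one paced reaction-diffusion recording."""
    stim_site = (geometry.height // 2, 2)
    n_beats = config.warmup_beats + config.record_beats
    proto = PacingProtocol(kind="burst", s1_count=n_beats, s1s1=config.apd_pcl,
                           stim_site=stim_site,
                           steady_beats_before_acquisition=config.warmup_beats)
    sim = simulate_tissue(geometry, cell, proto, noise_snr_db=config.noise_snr_db,
                          seed=seed, record_tail_ms=450.0, keep_truth_stacks=False,
                          compute_ecg=False)
    out = {}
    for movie, label in ((sim.vm_movie, "apd80"), (sim.cai_movie, "catd80")):
        # mask from the unfiltered normalized movie (the SNR estimator
        # assumes white noise); features from the filtered one
        mask = build_quality_mask(preprocess(movie, 1, 1), config.snr_threshold_db)
        pp = preprocess(movie, spatial_kernel_px=3, temporal_window_frames=3)
        feats = beat_feature_table(pp, mask, stim_times=sim.truth["stim_times"],
                                   site_stride=config.site_stride)
        agg = aggregate_sites(feats, "duration", min_sites=25,
                              steady_from_beat=config.warmup_beats)
        out[label] = agg
        if label == "catd80":
            out["tau_ca"] = _tau_from_final_beat(pp, feats)
        else:
            out["_vm_feats"] = feats
    out["truth_tau_ca"] = cell.tau_ca_eff
    return out


def _tau_from_final_beat(pp_movie, feats: pd.DataFrame, min_sites: int = 25,
                         max_resid_rms: float = 0.05) -> dict:
    taus = []
    for (r, c), site in feats[feats["valid"] & feats["paced"]].groupby(["row", "col"]):
        last = site.sort_values("beat").iloc[-1]
        fit = fit_ca_decay(pp_movie.data[:, int(r), int(c)], last["activation_time"],
                           pp_movie.frame_interval)
        if not fit.valid:
            continue
        n_pts = max(1, int((fit.fit_window[1] - fit.fit_window[0])
                           / pp_movie.frame_interval))
        if np.sqrt(fit.rss / n_pts) > max_resid_rms or fit.amplitude < 0.2:
            continue  # mis-windowed or truncated decays only add noise
        taus.append(fit.tau)
    if len(taus) < min_sites:
        from .movie import InsufficientSitesError

        raise InsufficientSitesError(f"tau fits at {len(taus)} sites < {min_sites}")
    taus = np.asarray(taus)
    return {"mean": float(taus.mean()), "sd": float(taus.std(ddof=1)),
            "n_sites": int(len(taus))}


def measure_erp(cell: CellModelParams, config: StudyConfig) -> float:
    """Refractory-period scan on a uniform conduction strip."""
    h0, w0 = config.erp_strip
    strip = TissueGeometry(height=h0, width=w0, pixel_pitch=config.pixel_pitch)
    return measure_true_erp(
        strip, cell, s1s1=config.erp_s1s1, s2_start=config.erp_scan_start,
        s2_step=config.erp_scan_step, s1_count=config.erp_s1_count,
        stim_site=(h0 // 2, 2), stim_amplitude=config.erp_stim_amplitude,
        strategy="bisect")


def measure_alternans_threshold(rmap: RestitutionMap, config: StudyConfig,
                                site_apd_shift: np.ndarray) -> float:
    provider = cable_movie_provider(rmap, n_beats=60, discard=40,
                                    site_apd_shift=site_apd_shift,
                                    min_capture_fraction=0.6)
    res = find_alternans_threshold(provider, config.pcl_start, config.pcl_step,
                                   config.pcl_min)
    return res.threshold_pcl


def test_inducibility(rmap: RestitutionMap, threshold_pcl: float,
                      config: StudyConfig, seed: int) -> dict:
    """Premature-beat challenge on the heart's CV-restitution cable.

    At one scan step below the alternans threshold the cable is paced
    to steady state and challenged with a premature stimulus.  If the
    substrate is spatially discordant and the premature beat blocks
    mid-cable (unidirectional block at the nodal line), reentry starts:
    a run of rapid post-stimulus beats is rendered into the pseudo-ECG
    for the rhythm classifier.  Without discordant block no arrhythmia
    follows.
    """
    rng = np.random.default_rng(seed)
    induced_mechanism = False
    if np.isfinite(threshold_pcl):
        # challenge just below the conducting cable's own alternans onset,
        # where a discordant substrate (if any) is fully developed
        pcl = rmap.alternans_onset_pcl() - config.induction_challenge_delta
        n_sites, n_beats = 50, 120
        stim = np.append(np.arange(n_beats) * pcl, (n_beats - 1) * pcl + 0.8 * pcl)
        res = run_restitution_cable(rmap, pcl, n_beats, n_sites=n_sites,
                                    stim_times=stim)
        steady = res[(res["beat"] >= n_beats - 8) & (res["beat"] < n_beats)]
        profile = steady.groupby("site").apply(_signed_alternation, include_groups=False)
        signs = np.sign(profile.dropna().to_numpy())
        discordant = bool((signs > 0).any() and (signs < 0).any())
        prem = res[res["beat"] == n_beats].sort_values("site")["captured"].to_numpy()
        mid_block = bool(prem.any() and (~prem).any()
                         and 2 <= int(np.argmin(prem)) <= n_sites - 3)
        induced_mechanism = discordant and mid_block
    # render the post-protocol rhythm and let the classifier decide
    last_stim = 2000.0
    stim_times = np.arange(0.0, last_stim + 1.0, 300.0)
    beats = list(stim_times + 8.0)
    if induced_mechanism:
        if rng.uniform() < config.vf_probability:
            cycles = rng.uniform(60.0, 140.0, size=config.vt_beats + 6)
        else:
            cycles = rng.normal(config.vt_cycle_ms, 2.0, size=config.vt_beats)
        t = last_stim + 8.0 + 0.8 * 300.0
        for cyc in cycles:
            t += max(cyc, 40.0)
            beats.append(t)
    duration = (beats[-1] if beats else last_stim) + 400.0
    ecg = ecg_from_beats(np.asarray(beats), duration, noise_sd=0.05, seed=seed)
    detected = detect_ecg_beats(ecg, stim_times=stim_times)
    post = detected[detected["time"] > last_stim + 60.0]["time"].to_numpy()
    return {"beat_times": post, "baseline_cycle": 300.0,
            "mechanism_induced": induced_mechanism}


def _signed_alternation(group: pd.DataFrame) -> float:
    apd = group.sort_values("beat")["apd"].to_numpy()
    if len(apd) < 4 or np.any(~np.isfinite(apd)):
        return np.nan
    vals = apd[: len(apd) - len(apd) % 2]
    return float(np.mean(vals[0::2] - vals[1::2]))


def measure_pvb_burden(rate_per_min: float, config: StudyConfig, seed: int) -> float:
    """Ambient-rhythm recording with Poisson ectopy, classified on ECG.

    Sinus beats tick at the configured cycle; ectopic events arrive as a
    Poisson process and fire early in the cycle (soon after local
    recovery, as border-zone triggered activity does), refractory events
    suppressed.  The burden is whatever the beat detector and
    prematurity rule recover — not the programmed rate.
    """
    rng = np.random.default_rng(seed)
    duration_ms = config.pvb_observe_min * 60_000.0
    cycle = config.sinus_cycle_ms
    sinus = np.arange(0.0, duration_ms, cycle)
    n_events = rng.poisson(rate_per_min * config.pvb_observe_min)
    refractory = 0.55 * cycle
    ect = []
    for _ in range(n_events):
        base = rng.choice(sinus)
        coupling = refractory + rng.exponential(0.08 * cycle)
        t = base + coupling
        if coupling < cycle - 10.0 and all(abs(t - e) > refractory for e in ect):
            ect.append(t)
    beats = np.sort(np.concatenate([sinus + 6.0, np.asarray(ect)]))
    ecg = ecg_from_beats(beats, duration_ms + 200.0, noise_sd=0.05, seed=seed)
    detected = detect_ecg_beats(ecg, stim_times=sinus)  # sinus beats act as "expected"
    return compute_pvb_burden(detected, config.pvb_observe_min)


# ---------------------------------------------------------------------------
# study driver


def run_study(config: StudyConfig | None = None, output_dir: str | Path | None = None,
              progress: bool = False) -> dict:
    """Run the full paired study; returns (and optionally writes) the report."""
    config = config or StudyConfig()
    geometry = config.geometry()
    hearts = draw_hearts(config)
    rows = []
    induction_recs = []
    for h_idx, heart in enumerate(hearts):
        for condition in config.conditions:
            seed = (heart.seed + 7919 * list(config.conditions).index(condition)) % (2**31)
            cell = heart.cell[condition]
            paced = measure_paced_features(geometry, cell, config, seed)
            erp = measure_erp(cell, config)
            thr = measure_alternans_threshold(heart.restitution[condition], config,
                                              heart.site_apd_shift)
            ind = test_inducibility(heart.restitution[condition], thr, config, seed)
            burden = measure_pvb_burden(heart.pvb_rate[condition], config, seed)
            induction_recs.append({"heart_id": heart.heart_id, "condition": condition,
                                   **{k: ind[k] for k in ("beat_times", "baseline_cycle")}})
            rows.append({
                "heart_id": heart.heart_id, "condition": condition,
                "apd80": paced["apd80"]["mean"], "apd80_sd_sites": paced["apd80"]["sd"],
                "catd80": paced["catd80"]["mean"],
                "tau_ca": paced["tau_ca"]["mean"],
                "truth_tau_ca": paced["truth_tau_ca"],
                "erp": erp,
                "alternans_threshold": thr,
                "pvb_burden": burden,
            })
            if progress:
                print(f"  {heart.heart_id} {condition}: APD {rows[-1]['apd80']:.1f} "
                      f"ERP {erp:.0f} tau {rows[-1]['tau_ca']:.1f} thr {thr:.0f}")
    table = pd.DataFrame(rows)
    inducibility = assess_inducibility(induction_recs)
    report = build_report(table, inducibility, config)
    if output_dir or config.output_dir:
        _write_outputs(Path(output_dir or config.output_dir), table, inducibility, report)
    return {"table": table, "inducibility": inducibility, "report": report}


def build_report(table: pd.DataFrame, inducibility: pd.DataFrame,
                 config: StudyConfig) -> dict:
    """Paired comparisons over hearts; metrics, tests, and directions."""
    cond_a, cond_b = config.conditions
    metrics, tests = {}, {}
    for name in ("erp", "apd80", "catd80", "tau_ca", "alternans_threshold", "pvb_burden"):
        pivot = table.pivot(index="heart_id", columns="condition", values=name).dropna()
        entry = {}
        for cond in (cond_a, cond_b):
            vals = pivot[cond].to_numpy()
            entry[cond] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                           "n": int(len(vals))}
        metrics[name] = entry
        sample = PairedSample(list(pivot.index), pivot[cond_a].to_numpy(),
                              pivot[cond_b].to_numpy())
        tres = paired_t_test(sample)
        tests[name] = {"test": "paired_t", "t": tres.t, "df": tres.df,
                       "p": tres.p_two_sided, "mean_diff": tres.mean_diff}
    ipos = inducibility.pivot(index="heart_id", columns="condition", values="induced")
    n_a = int(ipos[cond_a].sum())
    n_b = int(ipos[cond_b].sum())
    n = len(ipos)
    metrics["inducibility"] = {
        cond_a: {"induced": n_a, "n": n, "fraction": n_a / n},
        cond_b: {"induced": n_b, "n": n, "fraction": n_b / n},
        "direction": "decrease" if n_b < n_a else "increase" if n_b > n_a else "unchanged",
    }
    tests["inducibility"] = {
        "test": "fisher_exact",
        "p": fisher_exact(ContingencyTable2x2(n_a, n - n_a, n_b, n - n_b)),
        "table": [[n_a, n - n_a], [n_b, n - n_b]],
    }
    report = summarize(metrics, tests, config.to_dict())
    report["n_hearts"] = int(table["heart_id"].nunique())
    return report


def _write_outputs(outdir: Path, table: pd.DataFrame, inducibility: pd.DataFrame,
                   report: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "heart_metrics.csv", index=False)
    inducibility.to_csv(outdir / "inducibility.csv", index=False)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=_json_default))
    (outdir / "report.txt").write_text(report_to_text(report))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------
# bundled test fixtures


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Small ground-truthed datasets for tests and examples.

    Writes a paced 24x24 dual-channel recording, a discordant-alternans
    strip movie, a spiral-wave phase stack, and an ECG trace with an
    ectopic beat; returns a manifest with SHA-256 checksums.  Same seed,
    same bytes.
    """
    from .synth import discordant_alternans_recording, spiral_phase_movie

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "files": {}}

    geo = with_scar(24, 24, scar_center=(12.0, 7.0), scar_radius_px=4.0)
    cell = CellModelParams()
    proto = PacingProtocol(kind="burst", s1_count=6, s1s1=300.0, stim_site=(12, 20))
    sim = simulate_tissue(geo, cell, proto, noise_snr_db=20.0, seed=seed,
                          keep_truth_stacks=False)
    rec_path = outdir / "paced_24x24.h5"
    cio.write_recording(rec_path, vm=sim.vm_movie, cai=sim.cai_movie,
                        pseudo_ecg=sim.pseudo_ecg, stimulus_log=sim.stimulus_log)

    vm, truth = discordant_alternans_recording(noise_snr_db=25.0, seed=seed,
                                               premature_fraction=0.8)
    strip_path = outdir / "discordant_strip.h5"
    cio.write_movie(vm, strip_path, format="hdf5_container")
    (outdir / "discordant_truth.json").write_text(json.dumps(
        {"node_col": truth["node_col"], "block_site": truth["block_site"],
         "pcl": truth["pcl"]}, indent=1))

    spiral = spiral_phase_movie()
    np.save(outdir / "spiral_phase.npy", spiral)

    beats = np.array([0.0, 350.0, 700.0, 930.0, 1400.0, 1750.0])
    ecg = ecg_from_beats(beats, 2100.0, noise_sd=0.05, seed=seed)
    np.savetxt(outdir / "ecg_with_pvb.csv", np.column_stack(
        [np.arange(len(ecg)) * 2.0, ecg]), delimiter=",", header="time_ms,ecg",
        comments="")

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
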