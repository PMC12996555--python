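"""End-to-end orchestration: manifest I/O, resampling, both analyses.

The F0 analysis pools per-cycle instantaneous F0 values within each
(vowel, gender, group) cell, reports median/mean/sd per cell, the relative
deviation zeta of each statistic, and one-way ANOVA p-values on raw and
pooled-z-normalized values.  The duration analysis estimates per-speaker
VTLN warp factors from the sustained /A/ vowels, extracts the five
transition/steady-state features from the common sentences, and aggregates
them per (group, gender) cell.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from . import f0stats, transitions, vtln, zff
from .datatypes import ANALYSIS_RATE, Waveform

log = logging.getLogger("strokeprosody")

GROUPS = ("stroke", "control")
GENDERS = ("male", "female")
VOWEL_TYPES = ("A", "E", "I", "O", "U")
_SENTENCE_RE = re.compile(r"^S\d+$")
MANIFEST_COLUMNS = ("path", "speaker_id", "group", "gender", "age", "utterance_type")


@dataclass
class UtteranceRecord:
    path: str
    speaker_id: str
    group: str
    gender: str
    age: int
    utterance_type: str
    take: int = 1
    complete: bool = True

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.utterance_type not in VOWEL_TYPES and not _SENTENCE_RE.match(self.utterance_type):
            raise ValueError(
                f"utterance_type must be a vowel {VOWEL_TYPES} or S<n>, got {self.utterance_type!r}"
            )

    @property
    def is_vowel(self) -> bool:
        return self.utterance_type in VOWEL_TYPES

    @property
    def is_sentence(self) -> bool:
        return bool(_SENTENCE_RE.match(self.utterance_type))


@dataclass
class PipelineConfig:
    """Every tunable of the two analyses; JSON-serializable."""

    zff_window_s: float = 0.010
    min_strength_frac: float = 0.05
    f0_min: float = 50.0
    f0_max: float = 300.0
    f0_pooling: str = "cycles"          # or "speakers"
    mfcc_frame_s: float = 0.020
    mfcc_shift_s: float = 0.010
    n_coeff: int = 13
    rasta: bool = True
    energy_frac: float = 0.06
    delta_k: int = 2
    threshold_frac: float = 0.5
    min_len_frames: int = 2
    rta_mode: str = "literal"           # or "excess"
    msstr_mode: str = "ratio_of_means"  # or "mean_of_ratios"
    vtln_enabled: bool = True
    vtln_lp_order: int | None = None
    vtln_knee_frac: float = 0.85
    age_band: tuple | None = None       # (lo, hi) inclusive, years
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        if data.get("age_band") is not None:
            data["age_band"] = tuple(data["age_band"])
        return cls(**data)


def load_manifest(path, base_dir=None, check_files: bool = True) -> list:
    """Read and validate a CSV manifest into UtteranceRecords.

    Errors name the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty manifest")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    base = base_dir if base_dir is not None else os.path.dirname(os.fspath(path))
    records = []
    for i, row in df.iterrows():
        try:
            rec = UtteranceRecord(
                path=os.path.join(base, str(row["path"])),
                speaker_id=str(row["speaker_id"]),
                group=str(row["group"]),
                gender=str(row["gender"]),
                age=int(row["age"]),
                utterance_type=str(row["utterance_type"]),
                take=int(row.get("take", 1)),
                complete=bool(row.get("complete", True)),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
        if check_files and not os.path.exists(rec.path):
            raise ValueError(f"{path}: row {i + 1}: file not found: {rec.path}")
        records.append(rec)
    return records


def resample_to_analysis_rate(w: Waveform, target: int = ANALYSIS_RATE) -> Waveform:
    """Band-limited resampling to the 16 kHz analysis rate.

    Input already at the target rate passes through unchanged; rates below
    the target are rejected (upsampling clinical audio is not supported).
    """
    if w.sample_rate == target:
        return w
    if w.sample_rate < target:
        raise ValueError(f"unsupported sample rate {w.sample_rate} Hz (< {target} Hz)")
    g = np.gcd(w.sample_rate, target)
    y = resample_poly(w.samples, target // g, w.sample_rate // g)
    return Waveform(y, target, source_id=w.source_id)


def load_utterances(records) -> list:
    """Read each record's WAV and resample; returns (record, waveform) pairs."""
    return [(r, resample_to_analysis_rate(Waveform.read(r.path))) for r in records]


def pairs_from_cohort(cohort) -> list:
    """(UtteranceRecord, Waveform) pairs from an in-memory synthetic cohort."""
    return [
        (
            UtteranceRecord(
                path=u.path, speaker_id=u.speaker_id, group=u.group, gender=u.gender,
                age=u.age, utterance_type=u.utterance_type, take=u.take,
                complete=u.complete,
            ),
            u.waveform,
        )
        for u in cohort.utterances
    ]


def _apply_age_band(pairs, age_band):
    if age_band is None:
        return pairs
    lo, hi = age_band
    kept = [(r, w) for r, w in pairs if lo <= r.age <= hi]
    log.info("age band %s: %d of %d utterances retained", age_band, len(kept), len(pairs))
    return kept


@dataclass
class F0AnalysisResult:
    table: pd.DataFrame          # per (vowel, gender): group medians/means/sds
    zeta: pd.DataFrame           # per (vowel, gender): zeta per statistic
    anova: pd.DataFrame          # per (vowel, gender): F, p raw and z-normalized
    per_utterance: pd.DataFrame  # per-utterance F0 summaries
    per_speaker: pd.DataFrame    # per-speaker (mean, median, sd) feature vectors

    def write(self, outdir, prefix: str = "f0") -> None:
        os.makedirs(outdir, exist_ok=True)
        for name in ("table", "zeta", "anova", "per_utterance", "per_speaker"):
            getattr(self, name).to_csv(os.path.join(outdir, f"{prefix}_{name}.csv"), index=False)


def run_f0_analysis(pairs, config: PipelineConfig | None = None) -> F0AnalysisResult:
    """Epoch-based F0 analysis over all vowel utterances.

    ``pairs`` is a list of (UtteranceRecord, Waveform).  Statistics per
    (vowel, gender, group) cell pool the per-cycle F0 values of every
    utterance in the cell (``config.f0_pooling='speakers'`` pools
    per-utterance medians instead).
    """
    cfg = config or PipelineConfig()
    pairs = _apply_age_band([(r, w) for r, w in pairs if r.is_vowel], cfg.age_band)
    if not pairs:
        raise ValueError("no vowel utterances to analyse")
    contours = {}
    per_utt_rows = []
    for rec, w in pairs:
        w16 = resample_to_analysis_rate(w)
        contour = zff.extract_f0(
            w16, cfg.zff_window_s, cfg.min_strength_frac, cfg.f0_min, cfg.f0_max
        )
        if len(contour) == 0:
            log.info("unvoiced utterance skipped: %s", rec.path)
            continue
        contours[rec.path] = (rec, contour)
        s = f0stats.summarize_f0(contour, utterance_id=rec.path)
        per_utt_rows.append(
            {
                "utterance_id": rec.path, "speaker_id": rec.speaker_id,
                "vowel": rec.utterance_type, "group": rec.group, "gender": rec.gender,
                "age": rec.age, "mean": s.mean, "median": s.median, "sd": s.sd,
                "skewness": s.skewness, "kurtosis": s.kurtosis, "n_cycles": s.n_cycles,
            }
        )
    per_utterance = pd.DataFrame(per_utt_rows)
    if per_utterance.empty:
        raise ValueError("all utterances were unvoiced")

    table_rows, zeta_rows, anova_rows = [], [], []
    for vowel in VOWEL_TYPES:
        for gender in GENDERS:
            cell_values = {}
            for grp in GROUPS:
                vals = [
                    c.values
                    for rec, c in contours.values()
                    if rec.utterance_type == vowel and rec.gender == gender and rec.group == grp
                ]
                if not vals:
                    raise ValueError(f"empty cell (vowel={vowel}, gender={gender}, group={grp})")
                if cfg.f0_pooling == "speakers":
                    cell_values[grp] = np.array([float(np.median(v)) for v in vals])
                else:
                    cell_values[grp] = np.concatenate(vals)
            stat = {
                grp: {
                    "median": float(np.median(v)),
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)),
                }
                for grp, v in cell_values.items()
            }
            table_rows.append(
                {"vowel": vowel, "gender": gender,
                 **{f"{k}_{grp}": stat[grp][k] for k in ("median", "mean", "sd")
                    for grp in GROUPS}}
            )
            zeta_rows.append(
                {
                    "vowel": vowel, "gender": gender,
                    **{
                        f"zeta_{k}": f0stats.relative_deviation(
                            stat["stroke"][k], stat["control"][k]
                        )
                        for k in ("median", "mean", "sd")
                    },
                }
            )
            raw_groups = [cell_values["stroke"], cell_values["control"]]
            res_raw = f0stats.one_way_anova(raw_groups)
            res_z = f0stats.one_way_anova(f0stats.zscore_pooled(raw_groups))
            anova_rows.append(
                {
                    "vowel": vowel, "gender": gender, "f_stat": res_raw.f_stat,
                    "p_value": res_raw.p_value, "p_value_znorm": res_z.p_value,
                    "df_between": res_raw.df_between, "df_within": res_raw.df_within,
                }
            )

    per_speaker = (
        per_utterance.groupby(["speaker_id", "group", "gender"], as_index=False)[
            ["mean", "median", "sd"]
        ].mean()
    )
    return F0AnalysisResult(
        table=pd.DataFrame(table_rows), zeta=pd.DataFrame(zeta_rows),
        anova=pd.DataFrame(anova_rows), per_utterance=per_utterance,
        per_speaker=per_speaker,
    )


@dataclass
class DurationAnalysisResult:
    features: pd.DataFrame   # per-utterance RTD/RTA/TR/RSSD/RSSA
    summary: pd.DataFrame    # per (group, gender): MTD/MTA/MTR/MSSD/MSSTR
    anova: pd.DataFrame      # per (gender, feature): p-value stroke vs control
    warp_factors: pd.DataFrame

    def write(self, outdir, prefix: str = "duration") -> None:
        os.makedirs(outdir, exist_ok=True)
        for name in ("features", "summary", "anova", "warp_factors"):
            getattr(self, name).to_csv(os.path.join(outdir, f"{prefix}_{name}.csv"), index=False)


def estimate_warp_factors(pairs, config: PipelineConfig | None = None) -> dict:
    """Per-speaker VTLN warp factor from the sustained /A/ vowels.

    Formant dispersion is measured on each speaker's /A/ utterance(s); the
    per-gender reference (mu, sigma) comes from control speakers only.
    """
    cfg = config or PipelineConfig()
    disp = {}
    meta = {}
    for rec, w in pairs:
        if rec.utterance_type != "A":
            continue
        w16 = resample_to_analysis_rate(w)
        track = vtln.estimate_formants(w16, lp_order=cfg.vtln_lp_order)
        d = vtln.formant_dispersion(track)
        disp.setdefault(rec.speaker_id, []).append(d)
        meta[rec.speaker_id] = (rec.gender, rec.group)
    if not disp:
        raise ValueError("no /A/ vowel utterances for warp-factor estimation")
    speakers = sorted(disp)
    d_mean = [float(np.mean(disp[s])) for s in speakers]
    genders = [meta[s][0] for s in speakers]
    groups = [meta[s][1] for s in speakers]
    refs = vtln.reference_stats(d_mean, genders, groups)
    return {
        s: vtln.warp_factor(d, refs[g], speaker_id=s)
        for s, d, g in zip(speakers, d_mean, genders)
    }


def run_duration_analysis(pairs, config: PipelineConfig | None = None) -> DurationAnalysisResult:
    """Transition/steady-state duration analysis over the common sentences.

    Only complete sentence utterances (types S0, S1, ...) enter; incomplete
    recordings are excluded.  When VTLN is enabled, each speaker's warp
    factor is estimated from their /A/ vowels and applied to the power
    spectrum before the mel filterbank.
    """
    cfg = config or PipelineConfig()
    pairs = _apply_age_band(pairs, cfg.age_band)
    alphas = {}
    if cfg.vtln_enabled:
        try:
            alphas = {s: wf.alpha for s, wf in estimate_warp_factors(pairs, cfg).items()}
        except ValueError as exc:
            log.info("VTLN disabled for this run: %s", exc)
    all_sentences = [(r, w) for r, w in pairs if r.is_sentence]
    n_incomplete = sum(1 for r, _ in all_sentences if not r.complete)
    if n_incomplete:
        log.info("excluding %d incomplete sentence recordings", n_incomplete)
    sentence_pairs = [(r, w) for r, w in all_sentences if r.complete]
    if not sentence_pairs:
        raise ValueError("no complete sentence utterances to analyse")
    expected_cells = {(r.group, r.gender) for r, _ in all_sentences}
    surviving = {(r.group, r.gender) for r, _ in sentence_pairs}
    for cell in sorted(expected_cells - surviving):
        raise ValueError(f"empty cell after completeness filtering: {cell}")

    rows = []
    for rec, w in sentence_pairs:
        w16 = resample_to_analysis_rate(w)
        alpha = alphas.get(rec.speaker_id, 1.0)
        m = transitions.compute_mfcc(
            w16, vtln_alpha=alpha, frame_s=cfg.mfcc_frame_s, shift_s=cfg.mfcc_shift_s,
            n_coeff=cfg.n_coeff, rasta=cfg.rasta, knee_frac=cfg.vtln_knee_frac,
        )
        m = transitions.discard_silence(m, energy_frac=cfg.energy_frac)
        curve = transitions.cepstral_difference(m, K=cfg.delta_k)
        regions = transitions.find_regions(
            curve, threshold_frac=cfg.threshold_frac, min_len_frames=cfg.min_len_frames
        )
        feats = transitions.transition_features(
            regions, curve, frame_shift_s=cfg.mfcc_shift_s, rta_mode=cfg.rta_mode,
            utterance_id=rec.path,
        )
        rows.append(
            {
                "utterance_id": rec.path, "speaker_id": rec.speaker_id,
                "sentence": rec.utterance_type, "group": rec.group,
                "gender": rec.gender, "age": rec.age, "complete": rec.complete,
                "rtd": feats.rtd, "rta": feats.rta, "tr": feats.tr,
                "rssd": feats.rssd, "rssa": feats.rssa,
            }
        )
    features = pd.DataFrame(rows)
    summary = transitions.group_summary(features, msstr_mode=cfg.msstr_mode)

    anova_rows = []
    for gender in GENDERS:
        sub = features[features["gender"] == gender]
        for feat in ("rtd", "rta", "tr", "rssd", "rssa"):
            groups_vals = [
                sub.loc[sub["group"] == grp, feat].to_numpy() for grp in GROUPS
            ]
            if any(g.size < 2 for g in groups_vals):
                continue
            res = f0stats.one_way_anova(groups_vals)
            anova_rows.append(
                {"gender": gender, "feature": feat, "f_stat": res.f_stat,
                 "p_value": res.p_value}
            )
    warp_df = pd.DataFrame(
        [{"speaker_id": s, "alpha": a} for s, a in sorted(alphas.items())]
    )
    return DurationAnalysisResult(
        features=features, summary=summary, anova=pd.DataFrame(anova_rows),
        warp_factors=warp_df,
    )
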