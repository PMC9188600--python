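"""End-to-end orchestration: extract features, test groups, classify.

The front-end standardizes each recording (0.5 s center trim, 50 Hz-4 kHz
4th-order Butterworth band-pass) and extracts the 17 per-recording
features: intensity SD/range, jitter (abs/rel), shimmer (dB/rel), pitch
SD, HNR, NHR, SD(F1..F4) and VTL(F1..F4). Downstream, group differences
are tested nonparametrically and classes are separated with a
leave-one-out Gaussian SVM, optionally on the ten highest Relief-F-ranked
features.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import glottal, intensity, preprocess, tract
from .audio import AudioSegment, read_wav
from .errors import PhonemarkError
from .synth import generate_dataset

__all__ = ["RunConfig", "FEATURE_SETS", "extract_features", "build_feature_table",
           "load_directory", "run_pipeline"]

log = logging.getLogger(__name__)

FEATURE_SETS = {
    "intensity": ["intensity_sd", "intensity_range"],
    "glottal": ["jitter_abs", "jitter_rel", "shimmer_db", "shimmer_rel",
                "pitch_sd", "hnr", "nhr"],
    "formant_sd": ["sd_f1", "sd_f2", "sd_f3", "sd_f4"],
    "vtl": ["vtl_f1", "vtl_f2", "vtl_f3", "vtl_f4"],
}
FEATURE_SETS["all"] = (FEATURE_SETS["intensity"] + FEATURE_SETS["glottal"]
                       + FEATURE_SETS["formant_sd"] + FEATURE_SETS["vtl"])


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run; defaults are the reference
    extraction settings (0.5 s trim, 50-4000 Hz band, 5.5 kHz formant
    ceiling with 25 ms/6.25 ms framing, 75-500 Hz pitch range, Gaussian-
    kernel SVM with leave-one-out validation, Relief-F k=10/top-10)."""

    input_dir: str | None = None
    out_dir: str | None = None
    trim_duration: float = 0.5
    band_lo: float = 50.0
    band_hi: float = 4000.0
    zero_phase: bool = False
    pitch_fmin: float = 75.0
    pitch_fmax: float = 500.0
    formant: tract.FormantSettings = field(default_factory=tract.FormantSettings)
    svm_gamma: float | str = "scale"
    svm_c: float = 1.0
    relieff_k: int = 10
    relieff_top_n: int = 10
    feature_set: str = "all"
    phonemes: tuple[str, ...] = ("a",)
    combine: bool = False
    n_per_class: int = 20
    n_repetitions: int = 1
    synth_duration: float = 1.0
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "formant" in payload:
            payload["formant"] = tract.FormantSettings(**payload["formant"])
        if "phonemes" in payload:
            payload["phonemes"] = tuple(payload["phonemes"])
        return cls(**payload)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["phonemes"] = list(self.phonemes)
        return json.dumps(d, indent=1, default=str)


def extract_features(seg: AudioSegment, config: RunConfig | None = None) -> dict:
    """The 17 voice features of one recording.

    Deterministic for fixed input and config. Raises a
    :class:`~phonemark.errors.PhonemarkError` subclass on unvoiced or
    too-short input; callers log and skip such recordings.
    """
    cfg = config or RunConfig()
    trimmed = preprocess.trim_uniform(seg, cfg.trim_duration)
    seg = preprocess.bandpass(trimmed, cfg.band_lo, cfg.band_hi,
                              zero_phase=cfg.zero_phase)

    contour = intensity.intensity_contour(seg)
    int_sd, int_range = intensity.intensity_stats(contour)

    pt = glottal.detect_pulses(seg, cfg.pitch_fmin, cfg.pitch_fmax)
    harm = glottal.harmonicity(seg, pt)

    # Formants are fit on the trimmed, unfiltered signal: the 4 kHz band
    # edge would otherwise sit inside the 5.5 kHz analysis band and bias
    # the upper formants toward the filter cliff.
    track = tract.formant_track(trimmed, cfg.formant)
    f_means, f_sds = tract.formant_stats(track)
    vtl = tract.vtl_from_formants(f_means)

    feats = {
        "intensity_sd": int_sd,
        "intensity_range": int_range,
        "jitter_abs": glottal.jitter_abs(pt),
        "jitter_rel": glottal.jitter_rel(pt),
        "shimmer_db": glottal.shimmer_db(pt),
        "shimmer_rel": glottal.shimmer_rel(pt),
        "pitch_sd": glottal.pitch_sd(pt),
        "hnr": harm.hnr_db,
        "nhr": harm.nhr,
    }
    for i in range(4):
        feats[f"sd_f{i + 1}"] = float(f_sds[i])
    for i in range(4):
        feats[f"vtl_f{i + 1}"] = float(vtl.vtl[i])
    return feats


def load_directory(root) -> list[dict]:
    """Scan ``<root>/<group>/<subject>/<phoneme>_<rep>.wav`` into records."""
    root = Path(root)
    records = []
    for wav in sorted(root.glob("*/*/*.wav")):
        group, subject = wav.parent.parent.name, wav.parent.name
        stem = wav.stem
        if "_" in stem:
            phoneme, _, rep = stem.rpartition("_")
            rep = int(rep) if rep.isdigit() else 0
        else:
            phoneme, rep = stem, 0
        records.append(dict(group=group, subject=subject, phoneme=phoneme,
                            repetition=rep, path=wav, segment=None, truth=None))
    return records


def build_feature_table(records, config: RunConfig | None = None) -> tuple[pd.DataFrame, list[dict]]:
    """Extract features for every record; returns (table, skip reports).

    Each record needs group/subject/phoneme/repetition plus either a
    ``segment`` (AudioSegment) or a ``path`` to a WAV file. Failures are
    logged per recording, never silently dropped.
    """
    cfg = config or RunConfig()
    rows, skipped = [], []
    for rec in records:
        seg = rec.get("segment")
        if seg is None:
            seg = read_wav(rec["path"])
        try:
            feats = extract_features(seg, cfg)
        except PhonemarkError as exc:
            reason = f"{type(exc).__name__}: {exc}"
            log.warning("skipping %s/%s %s_%s: %s", rec["group"], rec["subject"],
                        rec["phoneme"], rec["repetition"], reason)
            skipped.append(dict(subject_id=rec["subject"], group=rec["group"],
                                phoneme=rec["phoneme"], repetition=rec["repetition"],
                                reason=reason))
            continue
        rows.append(dict(subject_id=rec["subject"], group=rec["group"],
                         phoneme=rec["phoneme"], repetition=rec["repetition"], **feats))
    return pd.DataFrame(rows), skipped


def _select_features(table: pd.DataFrame, config: RunConfig) -> list[str]:
    if config.feature_set == "relieff_top10":
        ranked = _classify.relief_f(table, k=config.relieff_k)
        return [name for name, _ in ranked[: config.relieff_top_n]]
    if config.feature_set in FEATURE_SETS:
        wanted = FEATURE_SETS[config.feature_set]
        available = _classify.feature_columns(table)
        # plain tables carry the names directly; combined tables carry them
        # phoneme-prefixed
        selected = [c for c in available
                    if c in wanted or any(c.endswith("_" + f) for f in wanted)]
        if not selected:
            raise PhonemarkError(
                f"feature set {config.feature_set!r} matches no table column")
        return selected
    raise PhonemarkError(f"unknown feature set {config.feature_set!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run synth/load -> extract -> stats -> classify; write artifacts.

    Returns a dict with the feature table, the per-feature statistics
    table, the classification reports (per phoneme and, if requested,
    combined), and the skip log. When ``config.out_dir`` is set, the same
    artifacts are written there as CSV/JSON along with the resolved config.
    """
    cfg = config
    if cfg.input_dir is not None:
        records = load_directory(cfg.input_dir)
        if not records:
            raise PhonemarkError(f"no recordings found under {cfg.input_dir}")
    else:
        records = generate_dataset(None, cfg.n_per_class, seed=cfg.seed,
                                   phonemes=cfg.phonemes,
                                   n_repetitions=cfg.n_repetitions,
                                   duration=cfg.synth_duration, write_files=False)

    table, skipped = build_feature_table(records, cfg)
    if len(table) == 0:
        raise PhonemarkError("no recording yielded features; see skip log")

    from .stats import group_feature_table

    stats_table = group_feature_table(table)

    reports = {}
    per_phoneme = {p: t for p, t in table.groupby("phoneme")}
    for phoneme, sub in per_phoneme.items():
        sub = sub.reset_index(drop=True)
        feats = _select_features(sub, cfg)
        reports[phoneme] = _classify.loocv_svm(sub, gamma=cfg.svm_gamma,
                                               c=cfg.svm_c, features=feats)
    if cfg.combine and len(per_phoneme) > 1:
        base = (FEATURE_SETS.get(cfg.feature_set)
                if cfg.feature_set in FEATURE_SETS else None)
        combined = _classify.combine_phonemes(
            [per_phoneme[p].reset_index(drop=True) for p in cfg.phonemes
             if p in per_phoneme],
            feature_subset=base,
        )
        feats = (_select_features(combined, cfg)
                 if cfg.feature_set == "relieff_top10" else None)
        reports["+".join(cfg.phonemes)] = _classify.loocv_svm(
            combined, gamma=cfg.svm_gamma, c=cfg.svm_c, features=feats)

    result = dict(features=table, stats=stats_table, reports=reports, skipped=skipped)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        stats_table.to_csv(out / "stats.csv", index=False)
        (out / "config.json").write_text(cfg.to_json())
        (out / "reports.json").write_text(json.dumps(
            {k: r.to_dict() for k, r in reports.items()}, indent=1))
        if skipped:
            pd.DataFrame(skipped).to_csv(out / "skipped.csv", index=False)
    return result
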