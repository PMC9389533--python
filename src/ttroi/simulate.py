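"""Synthetic per-frame detection streams with video-level structure.

No real endoscopy streams are deposited, so the pipeline is exercised on a
two-layer generative model:

1. **Viewing process** — each ~5-minute video (log-normal duration, median
   300 s) contains a small number of lesion-viewing episodes (Poisson count,
   min 1; gamma durations, mean 25 s) during which the endoscope dwells on the
   lesion; the rest of the time it sees background mucosa.
2. **Emission confusion** — every frame draws a tag from a per-tissue-class
   confusion row P(tag | viewed tissue), mixed with first-order persistence:
   with probability ``persistence_rho`` a frame copies the previous frame's
   tag, which clumps tags the way a detector's output clumps in time.

False positives in non-cancerous videos are modelled as rare *bursts* — with
a per-video occurrence probability the whole emission row temporarily switches
to the cancer-tissue row — rather than i.i.d. frame noise: over ~9,000 frames
any realistic per-frame error rate would tag essentially every benign video at
least once, whereas the calibration requires most benign videos to carry no
cancer tag at all (78.1% with zero ROIs; burst probability 14/64 ≈ 0.219 on
the default cohort mix).  Symmetrically, a cancerous video is "silent" (its
episodes emit from the benign row, so no cancer tags) with probability 0.094,
mirroring the 5/53 cancer videos without an ROI.

Determinism: the cohort seed and a per-video index feed
``numpy.random.SeedSequence``, so identical (spec, params, seed) reproduce the
cohort bit for bit, and per-video draws are consumed in a fixed order that
does not depend on the probability values — raising P(cancer | EGC) with the
same seed can only add cancer tags, never remove them (a monotone coupling
used by the calibration tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .streams import (
    CANCER_PATHOLOGIES,
    PATHOLOGIES,
    FrameSeries,
    VideoMeta,
)

__all__ = ["SimParams", "CohortSpec", "default_params", "default_cohort",
           "simulate_video", "simulate_cohort"]

#: Viewed tissue classes, indexing the emission rows.
TISSUES = ("EGC", "benign_lesion", "background")
_EGC, _BENIGN_TISSUE, _BACKGROUND_TISSUE = range(3)

# Per-frame confusion rows P(tag | tissue) over (cancer, benign, background,
# none).  The cancer column is zero outside cancerous tissue: benign-video
# false positives enter only through bursts (see module docstring).  These are
# calibration choices constrained by the video-level statistics, not measured
# per-frame rates.
DEFAULT_EMISSION: dict[str, tuple[float, float, float, float]] = {
    "EGC": (0.85, 0.06, 0.05, 0.04),
    "benign_lesion": (0.0, 0.75, 0.15, 0.10),
    "background": (0.0, 0.03, 0.77, 0.20),
}

# Burst-probability overrides reproducing the false-positive allocation:
# 6/16 for atrophy+IM and 4/7 for LGIN (the subtypes the detector confuses
# with cancer), 4/41 for the remaining benign subtypes — 14/64 ≈ 0.219 overall
# on the default cohort mix.
DEFAULT_FP_OVERRIDES: dict[str, float] = {
    "inflammation": 4 / 41,
    "atrophy": 4 / 41,
    "IM": 4 / 41,
    "atrophy_IM": 6 / 16,
    "LGIN": 4 / 7,
}

# Pathology → Vienna category used for synthetic metadata (benign → C1,
# low-grade neoplasia → C3, differentiated EGC → C4, poorly differentiated →
# C5); consistent with the C4/C5 = cancer gold standard.
_VIENNA_OF = {
    "inflammation": "C1",
    "atrophy": "C1",
    "IM": "C1",
    "atrophy_IM": "C1",
    "LGIN": "C3",
    "EGC_diff": "C4",
    "EGC_poor_diff": "C5",
}


@dataclass
class SimParams:
    """Generative-model parameters.

    Parameters
    ----------
    fps : float
        Nominal frame rate, frames/s (default 30, the detector's real-time
        throughput).
    duration_median_s, duration_sigma : float
        Log-normal video duration: median 300 s, log-scale sigma 0.4
        (117 videos then total ≈ 10 h of footage).  ``duration_sigma=0``
        fixes every duration at the median.
    episode_rate : float
        Poisson mean of lesion-viewing episodes per video (min 1).
    episode_mean_s, episode_shape : float
        Gamma episode duration, mean 25 s, shape 2.
    emission : dict
        P(tag | tissue) rows over (cancer, benign, background, none) for the
        tissue classes "EGC", "benign_lesion", "background"; each row sums
        to 1 within 1e-9.
    persistence_rho : float in [0, 1)
        Probability a frame copies the previous frame's tag (0 → i.i.d.).
    fp_burst_prob : float
        Marginal per-video probability that a non-cancerous video contains a
        false-cancer burst (default 0.219 = 14/64); used directly for
        pathologies without an entry in ``subtype_overrides``.
    fp_burst_mean_s : float
        Exponential mean burst duration (10 s).
    silent_lesion_prob : float
        Probability a cancerous video emits no cancer tags (episodes fall
        back to the benign emission row); default 0.094 = 5/53.
    subtype_overrides : dict
        Per-pathology overrides: ``{"pathology": {"fp_burst_prob": p}}`` or
        ``{"pathology": {"emission": {...}}}``.
    seed : int
        Default master seed when none is passed to :func:`simulate_cohort`.
    """

    fps: float = 30.0
    duration_median_s: float = 300.0
    duration_sigma: float = 0.4
    episode_rate: float = 3.0
    episode_mean_s: float = 25.0
    episode_shape: float = 2.0
    emission: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_EMISSION.items()})
    persistence_rho: float = 0.8
    fp_burst_prob: float = 0.219
    fp_burst_mean_s: float = 10.0
    silent_lesion_prob: float = 0.094
    subtype_overrides: dict = field(
        default_factory=lambda: {
            p: {"fp_burst_prob": v} for p, v in DEFAULT_FP_OVERRIDES.items()
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("duration_median_s", "episode_rate", "episode_mean_s",
                     "episode_shape", "fp_burst_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_sigma < 0:
            raise ValueError("duration_sigma must be non-negative")
        if not 0.0 <= self.persistence_rho < 1.0:
            raise ValueError("persistence_rho must be in [0, 1)")
        for name in ("fp_burst_prob", "silent_lesion_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        self._validate_emission(self.emission)
        for pathology, over in self.subtype_overrides.items():
            if pathology not in PATHOLOGIES:
                raise ValueError(f"override for unknown pathology {pathology!r}")
            for key, val in over.items():
                if key == "fp_burst_prob":
                    if not 0.0 <= val <= 1.0:
                        raise ValueError("override fp_burst_prob must be a probability")
                elif key == "emission":
                    self._validate_emission(val, partial=True)
                else:
                    raise ValueError(f"unknown override key {key!r}")

    @staticmethod
    def _validate_emission(emission: dict, partial: bool = False) -> None:
        if not partial and set(emission) != set(TISSUES):
            raise ValueError(f"emission must have rows for {TISSUES}")
        for tissue, row in emission.items():
            if tissue not in TISSUES:
                raise ValueError(f"unknown tissue class {tissue!r}")
            row = np.asarray(row, dtype=float)
            if row.shape != (4,) or np.any(row < 0) or np.any(row > 1):
                raise ValueError(f"emission row for {tissue!r} must be 4 probabilities")
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(f"emission row for {tissue!r} sums to {row.sum()!r}, not 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        # plain lists so the dict round-trips through YAML/JSON unchanged
        d["emission"] = {k: list(v) for k, v in d["emission"].items()}
        for over in d["subtype_overrides"].values():
            if "emission" in over:
                over["emission"] = {k: list(v) for k, v in over["emission"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        params = cls(**d)
        params.validate()
        return params

    def _effective(self, pathology: str) -> tuple[np.ndarray, float]:
        """(emission matrix 3×4, burst probability) after subtype overrides."""
        over = self.subtype_overrides.get(pathology, {})
        emission = dict(self.emission)
        emission.update(over.get("emission", {}))
        mat = np.array([emission[t] for t in TISSUES], dtype=float)
        return mat, float(over.get("fp_burst_prob", self.fp_burst_prob))


@dataclass
class CohortSpec:
    """Test-cohort composition: per-pathology video counts and covariate
    mixes.  Defaults reproduce the 117-video cohort (53 cancer, 64 benign)
    with its male-sex and upper-location margins; severity and range are
    drawn only for the atrophy+IM subtype (11/16 moderate-severe, 7/16
    diffuse)."""

    counts: dict = field(
        default_factory=lambda: {
            "inflammation": 24,
            "atrophy": 10,
            "IM": 7,
            "atrophy_IM": 16,
            "LGIN": 7,
            "EGC_poor_diff": 5,
            "EGC_diff": 48,
        }
    )
    male_prob: dict = field(
        default_factory=lambda: {"cancer": 45 / 53, "non_cancer": 40 / 64}
    )
    upper_prob: dict = field(
        default_factory=lambda: {"cancer": 24 / 53, "non_cancer": 24 / 64}
    )
    severity_moderate_prob: float = 11 / 16
    range_diffuse_prob: float = 7 / 16

    def validate(self) -> None:
        for pathology, n in self.counts.items():
            if pathology not in PATHOLOGIES:
                raise ValueError(f"unknown pathology {pathology!r}")
            if n < 0 or n != int(n):
                raise ValueError(f"count for {pathology!r} must be a non-negative integer")
        for d in (self.male_prob, self.upper_prob):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("covariate mixes must be probabilities")
        for v in (self.severity_moderate_prob, self.range_diffuse_prob):
            if not 0.0 <= v <= 1.0:
                raise ValueError("covariate mixes must be probabilities")

    @property
    def n_videos(self) -> int:
        return int(sum(self.counts.values()))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        spec = cls(**d)
        spec.validate()
        return spec


def default_params() -> SimParams:
    """The documented calibrated defaults."""
    return SimParams()


def default_cohort() -> CohortSpec:
    """The default 117-video cohort composition."""
    return CohortSpec()


def simulate_video(
    meta: VideoMeta,
    params: SimParams,
    seed,
    episodes: Sequence[tuple[float, float]] | None = None,
) -> FrameSeries:
    """One synthetic detection stream, deterministic in (meta, params, seed).

    ``episodes`` may force the lesion-viewing intervals (list of (start_s,
    end_s)), bypassing the sampled viewing process — useful for constructing
    streams with known TTROI.  ``seed`` is an integer or a
    ``numpy.random.SeedSequence``.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    # Fixed draw order (see module docstring): duration, episode count and
    # geometry, silent indicator, burst geometry, then the two frame streams.
    duration = float(
        params.duration_median_s
        * np.exp(rng.normal(0.0, 1.0) * params.duration_sigma)
    )
    n = max(1, int(np.floor(duration * params.fps)))
    t = np.arange(n) / params.fps

    k = max(1, int(rng.poisson(params.episode_rate)))
    ep_durs = rng.gamma(
        params.episode_shape, params.episode_mean_s / params.episode_shape, size=k
    )
    ep_starts = rng.uniform(0.0, 1.0, size=k) * np.maximum(duration - ep_durs, 0.0)
    u_silent = rng.uniform()
    u_burst = rng.uniform()
    burst_dur = rng.exponential(params.fp_burst_mean_s)
    burst_start = rng.uniform() * max(duration - burst_dur, 0.0)
    u_iid = rng.uniform(size=n)
    u_persist = rng.uniform(size=n)

    emission, fp_prob = params._effective(meta.pathology)
    is_cancer = meta.truth == "cancer"
    silent = is_cancer and u_silent < params.silent_lesion_prob
    lesion_tissue = _EGC if (is_cancer and not silent) else _BENIGN_TISSUE

    if episodes is None:
        episodes = [(s, s + d) for s, d in zip(ep_starts, ep_durs)]
    tissue = np.full(n, _BACKGROUND_TISSUE, dtype=np.int8)
    for start, end in episodes:
        i0, i1 = np.searchsorted(t, [start, end], side="left")
        if i1 < n and t[i1] <= end:
            i1 += 1
        tissue[i0:i1] = lesion_tissue
    if not is_cancer and u_burst < fp_prob:
        i0, i1 = np.searchsorted(
            t, [burst_start, min(burst_start + burst_dur, duration)], side="left"
        )
        tissue[i0 : max(i1, i0 + 1)] = _EGC

    cdf = np.cumsum(emission, axis=1)
    cdf[:, -1] = 1.0
    iid_codes = (u_iid[:, None] <= cdf[tissue]).argmax(axis=1).astype(np.int8)
    copy = u_persist < params.persistence_rho
    copy[0] = False
    src = np.maximum.accumulate(np.where(copy, -1, np.arange(n)))
    codes = iid_codes[src]

    return FrameSeries(
        meta.video_id, t, codes, duration_s=duration, fps=params.fps
    )


def _make_meta(pathology: str, video_id: str, spec: CohortSpec, rng) -> VideoMeta:
    truth = "cancer" if pathology in CANCER_PATHOLOGIES else "non_cancer"
    # draws in fixed order so metadata is reproducible
    u_sex, u_loc, u_sev, u_rng = rng.uniform(size=4)
    severity = rng_range = None
    if pathology == "atrophy_IM":
        severity = "moderate_severe" if u_sev < spec.severity_moderate_prob else "mild"
        rng_range = "diffuse" if u_rng < spec.range_diffuse_prob else "local"
    return VideoMeta(
        video_id=video_id,
        pathology=pathology,
        vienna=_VIENNA_OF[pathology],
        truth=truth,
        severity=severity,
        range=rng_range,
        location="upper" if u_loc < spec.upper_prob[truth] else "lower",
        sex="male" if u_sex < spec.male_prob[truth] else "female",
    )


def simulate_cohort(
    spec: CohortSpec | None = None,
    params: SimParams | None = None,
    seed: int | None = None,
) -> list[tuple[VideoMeta, FrameSeries]]:
    """Simulate one cohort: one (metadata, stream) pair per video.

    Per-video seeds derive from ``SeedSequence([seed, index])``, so any video
    can be regenerated independently of the rest.
    """
    spec = spec if spec is not None else default_cohort()
    params = params if params is not None else default_params()
    spec.validate()
    params.validate()
    master = int(params.seed if seed is None else seed)
    pathologies = [
        p for p in PATHOLOGIES for _ in range(int(spec.counts.get(p, 0)))
    ]
    out = []
    width = max(4, len(str(len(pathologies))))
    for i, pathology in enumerate(pathologies):
        meta_rng = np.random.default_rng(np.random.SeedSequence([master, i, 1]))
        meta = _make_meta(pathology, f"sim-{i:0{width}d}", spec, meta_rng)
        series = simulate_video(
            meta, params, np.random.SeedSequence([master, i, 0])
        )
        out.append((meta, series))
    return out
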