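"""Synthetic cohorts with the stratum structure of the training study.

The real training data are patient-level plasma measurements grouped into
four CSF A/T strata (A-/T-, A-/T+, A+/T-, A+/T+) whose sizes, means and
standard deviations are published in aggregate but whose records are not
deposited. This module generates cohorts with exactly that marginal
structure so that density fitting, cutoff derivation and classifier
training are testable end to end.

Distribution families follow the downstream modelling assumptions: the
Abeta42/40 ratio is drawn from a normal distribution (truncated to (0, 1)),
and p-tau181 from a gamma distribution moment-matched to the printed
mean/SD (shape = (mean/sd)^2, scale = sd^2/mean). Biomarkers are
independent within stratum by default; an optional Gaussian-copula rank
correlation between the ratio and p-tau181 is available.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import ConfigurationError, MissingColumnError

__all__ = [
    "StratumSpec",
    "CohortConfig",
    "default_unipg_specs",
    "generate_cohort",
    "generate_ams_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "STRATUM_TO_STATUS",
    "COHORT_COLUMNS",
]

#: Bijection between A/T stratum labels and (a_status, t_status) pairs.
STRATUM_TO_STATUS = {
    "A-/T-": ("A-", "T-"),
    "A-/T+": ("A-", "T+"),
    "A+/T-": ("A+", "T-"),
    "A+/T+": ("A+", "T+"),
}
STATUS_TO_STRATUM = {v: k for k, v in STRATUM_TO_STATUS.items()}

COHORT_COLUMNS = [
    "subject_id", "cohort", "stratum", "a_status", "t_status",
    "clinical_group", "abeta40", "abeta42", "ratio", "ptau181",
    "age", "sex", "kd", "albumin_tertile",
]

_ALBUMIN_LEVELS = ("low", "medium", "high")


@dataclass
class StratumSpec:
    """Per-stratum generating parameters (Table-1-shaped marginals)."""

    name: str
    n: int
    abeta40_mean: float
    abeta40_sd: float
    abeta42_mean: float
    abeta42_sd: float
    ratio_mean: float
    ratio_sd: float
    ptau_mean: float
    ptau_sd: float
    age_mean: float
    age_sd: float
    frac_female: float
    frac_kd: float
    albumin_tertile_fracs: tuple[float, float, float]  # (low, medium, high)

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"stratum {self.name}: n must be >= 0")
        if self.n > 0:
            for attr in ("abeta40_sd", "abeta42_sd", "ratio_sd", "ptau_sd", "age_sd"):
                if getattr(self, attr) <= 0:
                    raise ConfigurationError(
                        f"stratum {self.name}: {attr} must be > 0"
                    )
        for attr in ("frac_female", "frac_kd"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"stratum {self.name}: {attr}={v} outside [0, 1]"
                )
        fr = self.albumin_tertile_fracs
        if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"stratum {self.name}: albumin_tertile_fracs must be three "
                f"non-negative proportions summing to 1"
            )


@dataclass
class CohortConfig:
    """Configuration for :func:`generate_cohort`."""

    strata: list[StratumSpec]
    scale: float = 1.0
    seed: int = 0
    correlation_ratio_ptau: float = 0.0
    generate_ratio_directly: bool = True
    cohort_label: str = "UNIPG"

    def validate(self) -> None:
        if self.scale <= 0:
            raise ConfigurationError("scale must be > 0")
        if not -1.0 <= self.correlation_ratio_ptau <= 1.0:
            raise ConfigurationError("correlation_ratio_ptau outside [-1, 1]")
        for spec in self.strata:
            spec.validate()
        counts = [round(s.n * self.scale) for s in self.strata]
        if not any(c >= 1 for c in counts):
            raise ConfigurationError(
                "scale too small: every stratum rounds to 0 records"
            )

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        strata = [
            StratumSpec(**{**s, "albumin_tertile_fracs": tuple(s["albumin_tertile_fracs"])})
            for s in d.pop("strata")
        ]
        return cls(strata=strata, **d)


def default_unipg_specs() -> list[StratumSpec]:
    """The four CSF A/T strata of the 450-subject training cohort.

    Group sizes, biomarker means/SDs, ages, sex ratios, kidney-dysfunction
    counts and CSF/serum albumin tertile percentages are the published
    per-stratum summaries.
    """
    return [
        StratumSpec(
            name="A-/T-", n=126,
            abeta40_mean=301.0, abeta40_sd=76.0,
            abeta42_mean=25.7, abeta42_sd=7.3,
            ratio_mean=0.085, ratio_sd=0.012,
            ptau_mean=1.59, ptau_sd=1.3,
            age_mean=67.6, age_sd=8.1,
            frac_female=55 / 126, frac_kd=11 / 126,
            albumin_tertile_fracs=(0.37, 0.34, 0.29),
        ),
        StratumSpec(
            name="A-/T+", n=50,
            abeta40_mean=312.0, abeta40_sd=95.0,
            abeta42_mean=26.1, abeta42_sd=7.1,
            ratio_mean=0.085, ratio_sd=0.016,
            ptau_mean=1.68, ptau_sd=0.73,
            age_mean=69.6, age_sd=6.7,
            frac_female=20 / 50, frac_kd=1 / 50,
            albumin_tertile_fracs=(0.42, 0.29, 0.29),
        ),
        StratumSpec(
            name="A+/T-", n=48,
            abeta40_mean=319.0, abeta40_sd=63.0,
            abeta42_mean=22.5, abeta42_sd=5.5,
            ratio_mean=0.071, ratio_sd=0.012,
            ptau_mean=1.77, ptau_sd=0.72,
            age_mean=72.1, age_sd=5.6,
            frac_female=25 / 48, frac_kd=1 / 48,
            albumin_tertile_fracs=(0.27, 0.41, 0.32),
        ),
        StratumSpec(
            name="A+/T+", n=226,
            abeta40_mean=303.0, abeta40_sd=56.0,
            abeta42_mean=22.4, abeta42_sd=5.3,
            ratio_mean=0.074, ratio_sd=0.009,
            ptau_mean=2.92, ptau_sd=1.3,
            age_mean=72.3, age_sd=6.1,
            frac_female=146 / 226, frac_kd=15 / 226,
            albumin_tertile_fracs=(0.32, 0.32, 0.36),
        ),
    ]


def _moment_matched_gamma(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the gamma with the given first two moments."""
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


def _truncated_normal_01(rng: np.random.Generator, mean: float, sd: float,
                         size: int) -> np.ndarray:
    """Normal draws resampled until all fall in (0, 1).

    At the printed biomarker-ratio parameters the truncation mass is
    negligible (< 1e-8), so this loop almost never iterates.
    """
    out = rng.normal(mean, sd, size)
    bad = (out <= 0.0) | (out >= 1.0)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= 0.0) | (out >= 1.0)
    return out


def _draw_stratum(spec: StratumSpec, n: int, rng: np.random.Generator,
                  config: CohortConfig) -> pd.DataFrame:
    rho = config.correlation_ratio_ptau
    shape, scale = _moment_matched_gamma(spec.ptau_mean, spec.ptau_sd)

    if rho == 0.0:
        ratio = _truncated_normal_01(rng, spec.ratio_mean, spec.ratio_sd, n)
        ptau = rng.gamma(shape, scale, n)
    else:
        # Gaussian copula: correlated normals -> uniforms -> marginal ppfs.
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        u = stats.norm.cdf(z)
        lo = stats.norm.cdf(0.0, spec.ratio_mean, spec.ratio_sd)
        hi = stats.norm.cdf(1.0, spec.ratio_mean, spec.ratio_sd)
        ratio = stats.norm.ppf(lo + u[:, 0] * (hi - lo),
                               spec.ratio_mean, spec.ratio_sd)
        ptau = stats.gamma.ppf(u[:, 1], shape, scale=scale)

    if config.generate_ratio_directly:
        abeta40 = np.abs(rng.normal(spec.abeta40_mean, spec.abeta40_sd, n))
        abeta42 = ratio * abeta40
    else:
        abeta40 = np.abs(rng.normal(spec.abeta40_mean, spec.abeta40_sd, n))
        abeta42 = np.abs(rng.normal(spec.abeta42_mean, spec.abeta42_sd, n))
        ratio = abeta42 / abeta40

    age = rng.normal(spec.age_mean, spec.age_sd, n)
    sex = np.where(rng.random(n) < spec.frac_female, "F", "M")
    kd = rng.random(n) < spec.frac_kd
    albumin = rng.choice(_ALBUMIN_LEVELS, size=n,
                         p=np.asarray(spec.albumin_tertile_fracs, dtype=float))

    a_status, t_status = STRATUM_TO_STATUS.get(spec.name, ("unknown", "unknown"))
    return pd.DataFrame({
        "cohort": config.cohort_label,
        "stratum": spec.name,
        "a_status": a_status,
        "t_status": t_status,
        "clinical_group": "unknown",
        "abeta40": abeta40,
        "abeta42": abeta42,
        "ratio": ratio,
        "ptau181": ptau,
        "age": age,
        "sex": sex,
        "kd": kd,
        "albumin_tertile": albumin,
    })


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy per-subject DataFrame.

    Per stratum, ``round(n * scale)`` records are drawn. Reproducible:
    identical config and seed give byte-identical output.
    """
    config.validate()
    rng = substream(config.seed, "cohort")
    frames = []
    for spec in config.strata:
        n = int(round(spec.n * config.scale))
        if n == 0:
            continue
        frames.append(_draw_stratum(spec, n, rng, config))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id",
              [f"{config.cohort_label}-{i:06d}" for i in range(len(df))])
    return df[COHORT_COLUMNS]


def generate_ams_cohort(seed: int = 0) -> pd.DataFrame:
    """Generate the 80-subject external validation cohort (40 AD-dem + 40 CTRL).

    AD-dementia cases carry the A+/T+ biomarker distributions; controls
    carry A-/T- distributions but unknown CSF status (no CSF or amyloid-PET
    data exist for them), mirroring the case–control composition of the
    validation set. Ages are 65 +/- 4.2 y (cases) and 65 +/- 6.7 y
    (controls), 70% female in both arms.
    """
    unipg = {s.name: s for s in default_unipg_specs()}
    at = unipg["A+/T+"]
    nt = unipg["A-/T-"]

    def _mk(base: StratumSpec, name: str, age_mean: float, age_sd: float) -> StratumSpec:
        s = StratumSpec(**{**asdict(base),
                           "name": name, "n": 40,
                           "age_mean": age_mean, "age_sd": age_sd,
                           "frac_female": 0.70, "frac_kd": 0.0,
                           "albumin_tertile_fracs": base.albumin_tertile_fracs})
        return s

    cases = _mk(at, "A+/T+", 65.0, 4.2)
    ctrls = _mk(nt, "AMS-CTRL", 65.0, 6.7)  # unknown status label below

    config = CohortConfig(strata=[cases, ctrls], seed=seed, cohort_label="AMS")
    df = generate_cohort(config)
    is_case = df["stratum"] == "A+/T+"
    df.loc[is_case, "clinical_group"] = "AD-dem"
    df.loc[~is_case, ["stratum", "a_status", "t_status"]] = "unknown"
    df.loc[~is_case, "clinical_group"] = "CTRL"
    df.loc[~is_case, "albumin_tertile"] = "unknown"
    return df


# ---------------------------------------------------------------------------
# CSV round-tripping

def write_cohort_csv(df: pd.DataFrame, path, *, seed=None, config_hash=None) -> None:
    """Write a cohort CSV (comma, '.' decimal, UTF-8, 6 significant digits).

    Provenance (seed, config hash) is embedded as a leading '#' comment line.
    """
    buf = io.StringIO()
    if seed is not None or config_hash is not None:
        buf.write(f"# plasmaprob seed={seed} config={config_hash}\n")
    df.to_csv(buf, index=False, float_format="%.6g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_cohort_csv(path, required: Sequence[str] = ("subject_id",)) -> pd.DataFrame:
    """Read a cohort CSV, validating that required columns are present."""
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    for col in required:
        if col not in df.columns:
            raise MissingColumnError(col, f"file {path}, columns {list(df.columns)}")
    bad = None
    if "stratum" in df.columns:
        valid = set(STRATUM_TO_STATUS) | {"unknown"}
        mask = ~df["stratum"].isin(valid)
        if mask.any():
            bad = sorted(df.loc[mask, "stratum"].unique())
    if bad:
        raise ConfigurationError(
            f"unknown stratum label(s) {bad}; valid labels are "
            f"{sorted(set(STRATUM_TO_STATUS))} or 'unknown'"
        )
    return df
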