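"""Bioassay arithmetic: radicle-inhibition rates, activity bands, zone/MIC
summaries, and the screen's significance tests.

The phytotoxicity readout is the percent reduction of mean radicle length
relative to the water control,

    rate = (mean(control) - mean(treated)) / mean(control) * 100,

the standard germination-bioassay definition.  Rates at or below zero are
reported as NI (not inhibited).  Bands follow the screen's reporting style:
complete (exactly 100), strong [80, 100), potent [60, 80), weak [10, 60),
NI otherwise.  Note the weak band deliberately overlaps headline ">50%"
queries; ``count_over`` serves those.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ValidationError

BANDS = ("complete", "strong", "potent", "weak", "NI")

#: twofold dilution ladder used by the broth-dilution MIC assay (ug/mL)
MIC_LADDER = (100.0, 50.0, 25.0, 12.5, 6.25, 3.13, 1.56)


# ---------------------------------------------------------------------------
# radicle assay

@dataclass(frozen=True)
class RadicleAssay:
    """Replicate radicle lengths (mm) for one sample and its water control."""

    sample_id: str
    treated_lengths: tuple[float, ...]
    control_lengths: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.treated_lengths or not self.control_lengths:
            raise ValidationError(f"{self.sample_id}: empty replicate list")
        if any(x < 0 for x in self.treated_lengths + self.control_lengths):
            raise ValidationError(f"{self.sample_id}: negative radicle length")
        if not np.mean(self.control_lengths) > 0:
            raise ValidationError(
                f"{self.sample_id}: control mean is zero; rate undefined"
            )

    @property
    def replicates(self) -> int:
        return len(self.treated_lengths)


def band_of(rate_pct: float | None) -> str:
    """Activity band from an inhibition rate; ``None``/NaN/<10 -> NI."""
    if rate_pct is None or math.isnan(rate_pct):
        return "NI"
    if rate_pct >= 100:
        return "complete"
    if rate_pct >= 80:
        return "strong"
    if rate_pct >= 60:
        return "potent"
    if rate_pct >= 10:
        return "weak"
    return "NI"


@dataclass(frozen=True)
class InhibitionResult:
    """Inhibition rate (% of control radicle growth suppressed) with band."""

    sample_id: str
    rate_pct: float  # NaN when NI
    sd_pct: float
    band: str

    @property
    def is_ni(self) -> bool:
        return self.band == "NI" and math.isnan(self.rate_pct)

    @classmethod
    def from_rate(
        cls, sample_id: str, rate_pct: float | None, sd_pct: float = 0.0
    ) -> "InhibitionResult":
        if rate_pct is None or (isinstance(rate_pct, float) and math.isnan(rate_pct)):
            return cls(sample_id, math.nan, 0.0, "NI")
        return cls(sample_id, float(rate_pct), float(sd_pct), band_of(float(rate_pct)))


def inhibition_rate(assay: RadicleAssay) -> InhibitionResult:
    """Rate from replicate lengths; sd propagated from replicate-wise rates.

    Each treated replicate is scored against the control mean, so the
    reported mean rate equals the mean-length formula exactly; a rate <= 0
    is NI.
    """
    mc = float(np.mean(assay.control_lengths))
    per_rep = (mc - np.asarray(assay.treated_lengths, dtype=float)) / mc * 100.0
    rate = float(per_rep.mean())
    sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
    if rate <= 0:
        return InhibitionResult(assay.sample_id, math.nan, sd, "NI")
    return InhibitionResult(assay.sample_id, max(rate, 0.0), sd, band_of(rate))


def classify_bands(results: Iterable[InhibitionResult]) -> dict[str, int]:
    """Counts per activity band (all bands present, zero-filled)."""
    c = Counter(r.band for r in results)
    return {b: c.get(b, 0) for b in BANDS}


def count_over(
    results: Iterable[InhibitionResult], threshold: float, strict: bool = True
) -> int:
    """Number of samples with rate above (or at, if not strict) a threshold."""
    n = 0
    for r in results:
        if math.isnan(r.rate_pct):
            continue
        if r.rate_pct > threshold or (not strict and r.rate_pct == threshold):
            n += 1
    return n


def read_phytotoxicity(path: str | Path) -> list[InhibitionResult]:
    """Read a `strain_code  rate_pct  sd_pct` TSV with an NI sentinel."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("strain_code", "rate_pct"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        raw = str(row["rate_pct"]).strip()
        if raw.upper() == "NI":
            out.append(InhibitionResult.from_rate(row["strain_code"], None))
        else:
            sd = row.get("sd_pct")
            sd = 0.0 if sd is None or pd.isna(sd) else float(sd)
            out.append(InhibitionResult.from_rate(row["strain_code"], float(raw), sd))
    return out


# ---------------------------------------------------------------------------
# significance tests

def t_test(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> tuple[float, float]:
    """Two-sided two-sample t test; ``pooled`` (equal variance) or ``welch``.

    Degenerate zero-variance input with equal means gives (0.0, 1.0).
    """
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("t test needs at least 2 replicates per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if variant == "pooled":
        df = len(x) + len(y) - 2
        sp2 = ((len(x) - 1) * vx + (len(y) - 1) * vy) / df
        se2 = sp2 * (1 / len(x) + 1 / len(y))
    else:
        se2 = vx / len(x) + vy / len(y)
        if se2 > 0:
            df = se2**2 / (
                (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
            )
        else:
            df = len(x) + len(y) - 2
    if se2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(se2)
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass(frozen=True)
class PairwiseComparison:
    i: int
    j: int
    mean_diff: float
    t: float
    p: float
    significant: bool


@dataclass(frozen=True)
class AnovaLsdResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    alpha: float
    pairs: tuple[PairwiseComparison, ...]

    def significant_pairs(self) -> list[tuple[int, int]]:
        return [(c.i, c.j) for c in self.pairs if c.significant]


def one_way_anova_lsd(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> AnovaLsdResult:
    """One-way ANOVA with Fisher's (unprotected) LSD pairwise comparisons.

    Classical between/within sums-of-squares decomposition; each pair is
    compared with a two-sided t statistic on the pooled within-group mean
    square, flagged at ``alpha``.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in gs):
        raise ValidationError("each group needs at least 2 replicates")
    k = len(gs)
    n = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    dfb, dfw = k - 1, n - k
    if dfw <= 0:
        raise ValidationError("no residual degrees of freedom")
    msw = ssw / dfw
    if ssw == 0 and ssb == 0:
        raise ComputationError("indeterminate F: zero variance everywhere")
    if msw == 0:
        f, p = math.inf, 0.0
    else:
        f = (ssb / dfb) / msw
        p = float(stats.f.sf(f, dfb, dfw))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[i].mean() - gs[j].mean()
            se2 = msw * (1 / len(gs[i]) + 1 / len(gs[j]))
            if se2 == 0:
                t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
                pp = 1.0 if diff == 0 else 0.0
            else:
                t = diff / math.sqrt(se2)
                pp = float(2 * stats.t.sf(abs(t), dfw))
            pairs.append(
                PairwiseComparison(i, j, float(diff), float(t), pp, pp < alpha)
            )
    return AnovaLsdResult(
        f=float(f),
        p=p,
        df_between=dfb,
        df_within=dfw,
        ms_within=float(msw),
        alpha=alpha,
        pairs=tuple(pairs),
    )


# ---------------------------------------------------------------------------
# disc-diffusion zones and MIC

@dataclass(frozen=True)
class ZoneRecord:
    """One (sample, organism) disc-diffusion + MIC measurement.

    ``izd_mm`` is None for NI; an active zone must be at least the 6 mm disc.
    ``mic_censored`` marks a ">100 ug/mL" ceiling, which sorts last in MIC
    rankings.
    """

    sample_id: str
    organism: str
    izd_mm: float | None
    izd_sd_mm: float = 0.0
    mic_ug_ml: float | None = None
    mic_censored: bool = False
    role: str = "test"

    def __post_init__(self) -> None:
        if self.izd_mm is not None and self.izd_mm < 6.0:
            raise ValidationError(
                f"{self.sample_id}/{self.organism}: active IZD {self.izd_mm} mm "
                "below the 6 mm disc diameter"
            )
        if self.mic_ug_ml is not None and not self.mic_censored:
            if not any(math.isclose(self.mic_ug_ml, v) for v in MIC_LADDER):
                raise ValidationError(
                    f"{self.sample_id}/{self.organism}: MIC {self.mic_ug_ml} not on "
                    f"the twofold ladder {MIC_LADDER}"
                )

    @property
    def active(self) -> bool:
        return self.izd_mm is not None


def read_zone_table(path: str | Path) -> list[ZoneRecord]:
    """Read the `sample_id role organism mic_ug_ml izd_mm izd_sd_mm` TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        mic_raw = str(row["mic_ug_ml"]).strip()
        censored = mic_raw.startswith(">")
        mic = float(mic_raw.lstrip(">")) if mic_raw not in ("", "nan") else None
        izd_raw = str(row["izd_mm"]).strip()
        if izd_raw.upper() == "NI":
            izd, sd = None, 0.0
        else:
            izd = float(izd_raw)
            sd_raw = row.get("izd_sd_mm")
            sd = 0.0 if sd_raw is None or pd.isna(sd_raw) else float(sd_raw)
        out.append(
            ZoneRecord(
                sample_id=row["sample_id"],
                organism=row["organism"],
                izd_mm=izd,
                izd_sd_mm=sd,
                mic_ug_ml=mic,
                mic_censored=censored,
                role=row.get("role", "test"),
            )
        )
    return out


@dataclass(frozen=True)
class ScreenSummary:
    organisms: tuple[str, ...]
    samples: tuple[str, ...]
    active_organisms: dict[str, tuple[str, ...]]  # sample -> organisms hit
    n_active_any: int
    n_active_all: int
    ranking_by_izd: dict[str, tuple[str, ...]]  # organism -> samples, best first

    def actives(self) -> list[str]:
        return [s for s in self.samples if self.active_organisms[s]]


def screen_summary(zones: Iterable[ZoneRecord]) -> ScreenSummary:
    """Per-sample activity profile over a zone table.

    A sample is "active" on an organism when it produced a zone (non-NI).
    Per-organism rankings sort by IZD descending; samples with a censored
    MIC and no zone do not appear in the ranking.
    """
    zones = list(zones)
    organisms = tuple(dict.fromkeys(z.organism for z in zones))
    samples = tuple(dict.fromkeys(z.sample_id for z in zones))
    hit: dict[str, list[str]] = {s: [] for s in samples}
    for z in zones:
        if z.active:
            hit[z.sample_id].append(z.organism)
    active_organisms = {s: tuple(v) for s, v in hit.items()}
    n_any = sum(1 for s in samples if active_organisms[s])
    n_all = sum(1 for s in samples if len(active_organisms[s]) == len(organisms))
    ranking = {}
    for org in organisms:
        rows = [z for z in zones if z.organism == org and z.active]
        rows.sort(key=lambda z: (-z.izd_mm, z.sample_id))
        ranking[org] = tuple(z.sample_id for z in rows)
    return ScreenSummary(
        organisms=organisms,
        samples=samples,
        active_organisms=active_organisms,
        n_active_any=n_any,
        n_active_all=n_all,
        ranking_by_izd=ranking,
    )
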