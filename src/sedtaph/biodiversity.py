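"""Simpson-index diversity time series over secure, dated samples.

Diversity per sample is the inverse Simpson index 1/λ_s with
λ_s = Σ p_i² over taxon read proportions.  Samples are restricted to
secure, dated ones with enough reads, split into marine vs terrestrial by
their dominant guild, and averaged in a sliding window over calibrated age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .guilds import UNASSIGNED, GuildProfile


@dataclass
class DiversityPoint:
    window_center: float  # cal BP
    domain: str
    diversity: float      # mean 1/λ_s over member samples
    n_samples: int


def simpson_lambda(counts) -> float:
    """Simpson concentration λ_s = Σ p_i² of one sample's taxon counts."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = c / total
    return float((p ** 2).sum())


def inverse_simpson(counts) -> float:
    """Diversity 1/λ_s; equals the taxon count for a uniform composition."""
    return 1.0 / simpson_lambda(counts)


def classify_domain(profile: GuildProfile | pd.Series, marine_guild) -> str:
    """'marine' iff the marine guild has the strictly largest guild proportion."""
    if isinstance(profile, GuildProfile):
        props = dict(profile.proportions)
    else:
        props = {k: float(v) for k, v in profile.items() if k != UNASSIGNED}
    if marine_guild not in props:
        raise KeyError(f"marine guild {marine_guild!r} absent from profile")
    marine = props.pop(marine_guild)
    best_other = max(props.values(), default=0.0)
    return "marine" if marine > best_other else "terrestrial"


def diversity_series(
    counts: pd.DataFrame,
    metadata,
    profiles: pd.DataFrame | None = None,
    marine_guild: str | None = None,
    window: float = 1000.0,
    step: float = 500.0,
    min_reads: int = 50,
) -> pd.DataFrame:
    """Windowed mean diversity by domain over secure, dated samples.

    Eligible samples are secure, carry a numeric age, and have total reads
    strictly greater than ``min_reads``.  Window centers sit at multiples of
    ``step`` spanning the eligible age range; a sample joins every window
    with |age - center| <= window/2 (inclusive).  The domain comes from
    metadata when stated, otherwise from the dominant guild when a profile
    and marine guild are supplied.  Empty windows are omitted.
    """
    eligible = []
    for m in metadata:
        if m.security != "secure" or m.age_calBP is None:
            continue
        if m.sample_id not in counts.index:
            continue
        row = counts.loc[m.sample_id]
        if float(row.sum()) <= min_reads:
            continue
        domain = m.domain
        if domain == "unknown" and profiles is not None and marine_guild is not None \
                and m.sample_id in profiles.index:
            domain = classify_domain(profiles.loc[m.sample_id], marine_guild)
        eligible.append((m.sample_id, float(m.age_calBP), domain, inverse_simpson(row)))
    if not eligible:
        return pd.DataFrame(
            columns=["window_center_calBP", "domain", "mean_diversity", "n_samples"])
    ages = np.array([e[1] for e in eligible])
    half = window / 2.0
    # every center (a multiple of step) whose window can contain a sample
    lo = np.ceil((ages.min() - half) / step) * step
    hi = np.floor((ages.max() + half) / step) * step
    centers = np.arange(lo, hi + step / 2, step)
    rows = []
    for c in centers:
        members = [e for e in eligible if abs(e[1] - c) <= half]
        for domain in sorted({e[2] for e in members}):
            vals = [e[3] for e in members if e[2] == domain]
            rows.append({
                "window_center_calBP": float(c), "domain": domain,
                "mean_diversity": float(np.mean(vals)), "n_samples": len(vals),
            })
    return pd.DataFrame(rows)
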