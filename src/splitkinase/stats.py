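"""Genomic-survey arithmetic on printed domain counts.

Split histidine kinases are rare: surveys of sequenced genomes count a
handful of split CheAs among hundreds of complete ones, and of all
HisKA-domain proteins only a small fraction lack the HATPase domain while
retaining the phosphatase motif (candidate split bifunctional kinases).
This module performs only the arithmetic on user-supplied counts; it
never queries any sequence database.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def domain_fraction(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= count <= total):
        raise ValueError("count must satisfy 0 <= count <= total")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cluster_volume_percent(area_percent: float = 5.0) -> float:
    """Volume share of a spherical subregion from its cross-sectional area share.

    For a sphere-in-sphere geometry an area fraction a gives a radius
    fraction a^(1/2) and hence a volume fraction a^(3/2): a chemoreceptor
    cluster occupying 5% of the cell's cross-section occupies ~1% of its
    volume.  Returns a percentage.
    """
    if not (0.0 <= area_percent <= 100.0):
        raise ValueError("area_percent must be in [0, 100]")
    return float(100.0 * (area_percent / 100.0) ** 1.5)
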