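"""Small arithmetic helpers for headline summary statistics.

These are the routines that turn raw counts (lead-marker tallies, variant
catalogs, association tables) into the percentages and fold enrichments a
study reports; they exist as named functions so the arithmetic is tested
once and reused by the mapping, rare-association and reporting code.
"""

from __future__ import annotations

__all__ = ["percent", "fold_from_counts"]


def percent(numerator: int | float, denominator: int | float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    return round(100.0 * numerator / denominator, ndigits)


def fold_from_counts(
    hits: int, total: int, reference_hits: int, reference_total: int, ndigits: int = 6
) -> float:
    """(hits/total) / (reference_hits/reference_total): a rate ratio, e.g.
    lead-marker share over genomic abundance."""
    if 0 in (total, reference_total, reference_hits):
        raise ZeroDivisionError("fold enrichment undefined for zero counts")
    return round((hits / total) / (reference_hits / reference_total), ndigits)
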