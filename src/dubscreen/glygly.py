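"""Filtering and per-protein summarisation of GlyGly (diGly remnant) sites.

Tryptic digestion of a ubiquitinated protein leaves a Gly-Gly stub on the
modified lysine; a confidently localised GlyGly site is direct evidence of a
ubiquitination site.  Sites are filtered on decoy/contaminant flags, on
having any quantified intensity, and on the search engine's localization
probability (default cut-off: keep >= 0.75).  Filtered sites annotate
substrate records; they play no role in substrate calling itself.
"""

from __future__ import annotations

from typing import Sequence

from .tables_io import GlyGlySiteRow

__all__ = ["filter_glygly", "sites_per_protein", "glygly_summary"]

GLYGLY_REASONS = ("reverse", "contaminant", "no_intensity", "low_probability")


def filter_glygly(
    rows: Sequence[GlyGlySiteRow],
    min_probability: float = 0.75,
) -> tuple[list[GlyGlySiteRow], dict[str, int]]:
    """Remove decoy, contaminant, all-zero-intensity and poorly localised sites.

    A site with probability exactly at the cut-off is kept (only sites
    *below* ``min_probability`` are removed).  Input order is preserved;
    each removed row is logged once under the first matching reason.
    Idempotent.
    """
    kept: list[GlyGlySiteRow] = []
    log: dict[str, int] = {}
    for row in rows:
        if row.reverse_flag:
            reason = "reverse"
        elif row.contaminant_flag:
            reason = "contaminant"
        elif all(v <= 0 for v in row.intensity.values()):
            reason = "no_intensity"
        elif row.localization_probability < min_probability:
            reason = "low_probability"
        else:
            kept.append(row)
            continue
        log[reason] = log.get(reason, 0) + 1
    return kept, log


def sites_per_protein(kept: Sequence[GlyGlySiteRow]) -> dict[str, list[int]]:
    """Unique, ascending GlyGly positions per protein accession."""
    sites: dict[str, set[int]] = {}
    for row in kept:
        sites.setdefault(row.protein_id, set()).add(row.position)
    return {pid: sorted(positions) for pid, positions in sites.items()}


def glygly_summary(
    rows: Sequence[GlyGlySiteRow],
    min_probability: float = 0.75,
) -> dict[str, int]:
    """Pre- and post-filter site and protein counts (both reported because
    published totals do not state whether they are filtered)."""
    kept, _ = filter_glygly(rows, min_probability)
    return {
        "sites_total": len(rows),
        "proteins_total": len({r.protein_id for r in rows}),
        "sites_kept": len(kept),
        "proteins_kept": len({r.protein_id for r in kept}),
    }
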