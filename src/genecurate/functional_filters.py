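"""Gate gene models on functional evidence from a flat annotation file.

A model without a similarity-search hit or a gene-family assignment has no
independent support beyond its prediction; this filter removes such models
according to the chosen evidence mode.
"""

from __future__ import annotations

import logging

from .models import FilterLogEntry, GeneTable, make_entry
from .parsers import FunctionalMap

log = logging.getLogger(__name__)

MODES = ("similarity_or_family", "similarity_only", "family_only")


def filter_functional(
    table: GeneTable,
    fmap: FunctionalMap,
    mode: str = "similarity_or_family",
    strip_suffix: bool = True,
) -> tuple[GeneTable, FilterLogEntry]:
    """Keep models whose ID has the required functional hit(s).

    Lookup tries the transcript_id, then the gene_id; with ``strip_suffix``
    a trailing ``.pN``/``.tN`` is also dropped before giving up.  IDs absent
    from the map count as having no hit.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(fmap) == 0 and len(table) > 0:
        log.warning(
            "functional map is empty: every model will be removed by this filter"
        )

    survivors, removed = [], []
    for m in table:
        hit = fmap.lookup(m.transcript_id, strip_suffix=strip_suffix)
        if hit is None:
            hit = fmap.lookup(m.gene_id, strip_suffix=strip_suffix)
        if hit is None:
            removed.append((m.transcript_id, "not_in_functional_file"))
            continue
        similarity, family = hit
        if mode == "similarity_only":
            ok, reason = similarity, "no_similarity_hit"
        elif mode == "family_only":
            ok, reason = family, "no_family_hit"
        else:
            ok, reason = similarity or family, "no_similarity_or_family_hit"
        if ok:
            survivors.append(m)
        else:
            removed.append((m.transcript_id, reason))

    entry = make_entry("require_functional", {"mode": mode}, table, removed)
    return GeneTable(survivors, provenance=table.provenance), entry
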