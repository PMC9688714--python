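"""In-silico PCR: product sizes for a primer pair on a template.

The forward primer anneals to the plus strand and the reverse primer to
the minus strand (its reverse complement is searched on the plus strand).
Only exact matches are considered; product size spans the outer primer
ends, the convention gel-reported amplicon lengths follow.
"""

from __future__ import annotations

from .classify import COMPLEMENT


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def _find_all(template: str, query: str) -> list[int]:
    hits, start = [], template.find(query)
    while start != -1:
        hits.append(start)
        start = template.find(query, start + 1)
    return hits


def amplicon_sizes(template: str, forward: str, reverse: str,
                   max_size: int = 10_000) -> list[int]:
    """All exact-match product sizes for the primer pair, ascending."""
    template = template.upper()
    fwd_hits = _find_all(template, forward.upper())
    rev_hits = _find_all(template, reverse_complement(reverse))
    rev_len = len(reverse)
    sizes = []
    for f in fwd_hits:
        for r in rev_hits:
            size = r + rev_len - f
            if len(forward) <= size <= max_size:
                sizes.append(size)
    return sorted(sizes)
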