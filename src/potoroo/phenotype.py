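"""Worked arithmetic for knockdown phenotype counts.

Cytokinesis failure after depleting a midzone protein is scored as the
percentage of binucleated interphase cells in a treated population versus a
mock control.
"""

from __future__ import annotations


def binucleation_percentage(n_binucleated: int, n_total: int, digits: int = 1) -> float:
    """Percentage of binucleated cells, rounded to ``digits`` decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_binucleated <= n_total:
        raise ValueError("n_binucleated must be within [0, n_total]")
    return round(100.0 * n_binucleated / n_total, digits)
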