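"""Shared token normalization.

All matching in the pipeline (rule atoms, trigram shingles, gazetteer scan,
codebook keywords) operates on the same normalized token stream: whitespace
split, leading/trailing punctuation stripped, case-folded.  Internal
punctuation is kept so numerals like ``3,500,000`` survive as one token.
"""

from __future__ import annotations

import re

_STRIP = "\"'“”‘’.,;:!?()[]{}<>«»—–-…/\\|"

_NUM_RE = re.compile(r"[0-9][0-9,]*(?:\.[0-9]+)?")


def normalize_token(raw: str) -> str:
    return raw.strip(_STRIP).casefold()


def tokenize(text: str) -> list[str]:
    """Normalized tokens of ``text``; empty tokens (bare punctuation) dropped."""
    out = []
    for raw in text.split():
        tok = normalize_token(raw)
        if tok:
            out.append(tok)
    return out


def numeric_value(token: str) -> float | None:
    """Numeric value of a token like ``3,500,000`` or ``12.5``; None if not a number."""
    if not _NUM_RE.fullmatch(token):
        return None
    try:
        return float(token.replace(",", ""))
    except ValueError:  # pragma: no cover - fullmatch should prevent this
        return None
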