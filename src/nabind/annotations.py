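"""Annotation-keyword filtering for negative-set construction.

Candidate non-binder proteins are screened against their annotation text:
any entry mentioning a nucleic-acid-related term or GO identifier (e.g.
"DNA binding", "transcription") is removed, since it may well be a binder.
Matching is case-insensitive substring over all text columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd


def keyword_filter(
    annotations: Union[str, Path, pd.DataFrame],
    terms: Sequence[str],
    id_column: str = "id",
    report_path: Union[str, Path, None] = None,
) -> list[str]:
    """Return the ids whose annotation text matches none of ``terms``.

    ``annotations`` is a TSV (or DataFrame) with an id column and any
    number of free-text columns.  An empty term list retains everything.
    A removal report (id, matched term) is written when ``report_path`` is
    given.
    """
    if isinstance(annotations, (str, Path)):
        try:
            df = pd.read_csv(annotations, sep="\t", dtype=str)
        except Exception as exc:
            raise ValueError(f"malformed annotation TSV {annotations}: {exc}")
    else:
        df = annotations.astype(str)
    if id_column not in df.columns:
        raise ValueError(f"annotation table lacks an {id_column!r} column")
    ids = df[id_column].tolist()
    if len(ids) != len(set(ids)):
        raise ValueError("annotation ids are not unique")

    text_cols = [c for c in df.columns if c != id_column]
    blob = df[text_cols].fillna("").agg(" ".join, axis=1).str.lower()
    lowered = [t.lower() for t in terms]

    retained, removed = [], []
    for i, entry_id in enumerate(ids):
        hit = next((t for t, tl in zip(terms, lowered) if tl in blob.iloc[i]), None)
        if hit is None:
            retained.append(entry_id)
        else:
            removed.append((entry_id, hit))
    if report_path is not None:
        pd.DataFrame(removed, columns=["id", "matched_term"]).to_csv(
            report_path, sep="\t", index=False)
    return retained
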