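"""Canonical 10-20 scalp electrode labels and ordering helpers."""

from __future__ import annotations

# Classic 19-electrode 10-20 montage, in the canonical order used throughout
# this package (frontal -> posterior, left -> right within a row).
CANONICAL_19: tuple[str, ...] = (
    "FP1", "FP2",
    "F7", "F3", "FZ", "F4", "F8",
    "T3", "C3", "CZ", "C4", "T4",
    "T5", "P3", "PZ", "P4", "T6",
    "O1", "O2",
)

# Superset of valid referential 10-20 labels accepted by validation
# (includes the modern T7/T8/P7/P8 synonyms and common extensions).
VALID_1020: frozenset[str] = frozenset(
    CANONICAL_19
    + ("T7", "T8", "P7", "P8", "A1", "A2", "FPZ", "OZ", "CPZ", "FCZ")
)


def canonical_sort_key(label: str) -> tuple[int, str]:
    """Sort key: canonical 10-20 position first, then lexicographic."""
    lab = label.upper()
    try:
        return (CANONICAL_19.index(lab), lab)
    except ValueError:
        return (len(CANONICAL_19), lab)


def validate_labels(labels) -> list[str]:
    """Uppercase, check uniqueness and 10-20 membership. Returns clean list."""
    clean = [str(l).strip().upper() for l in labels]
    if len(set(clean)) != len(clean):
        dupes = sorted({l for l in clean if clean.count(l) > 1})
        raise ValueError(f"duplicate electrode labels: {dupes}")
    return clean
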