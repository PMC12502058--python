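"""Two-level cell-type taxonomy: base types and their subtypes.

A hierarchy is a mapping ``base type -> ordered list of subtypes``.  A base
type with no subtypes is a *terminal leaf*: the base-level call is the final
annotation for its cells, and the subtype classifier is bypassed.  Exactly
two levels are supported; deeper trees are rejected.

Index conventions
-----------------
Base types receive contiguous indices ``0..K_base-1`` in file order.
Subtypes receive contiguous *global* indices ``0..K_sub-1``, enumerating the
bases in order and each base's children in order, so the index ranges of
different lineages partition ``[0, K_sub)``.  Cells without a subtype label
(terminal-leaf bases, or unlabeled) carry the sentinel index ``-1`` and are
excluded from subtype losses and metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import ValidationError, canonical_json, sha256_of_text

#: sentinel subtype index for cells with no subtype label
NO_SUBTYPE = -1


@dataclass(frozen=True)
class CellTypeHierarchy:
    """Validated two-level taxonomy with name<->index maps at both levels."""

    base_names: tuple[str, ...]
    children: Mapping[str, tuple[str, ...]]
    subtype_to_base: Mapping[str, str] = field(init=False)
    K_base: int = field(init=False)
    K_sub: int = field(init=False)

    def __post_init__(self):
        if len(set(self.base_names)) != len(self.base_names):
            dup = _first_duplicate(self.base_names)
            raise ValidationError(f"duplicate base-type name: {dup!r}")
        inv: dict[str, str] = {}
        for base in self.base_names:
            for sub in self.children[base]:
                if sub in inv:
                    raise ValidationError(
                        f"subtype {sub!r} listed under both {inv[sub]!r} and {base!r}"
                    )
                inv[sub] = base
        all_subs = [s for b in self.base_names for s in self.children[b]]
        if len(set(all_subs)) != len(all_subs):
            raise ValidationError(f"duplicate subtype name: {_first_duplicate(all_subs)!r}")
        if set(all_subs) & set(self.base_names):
            clash = sorted(set(all_subs) & set(self.base_names))[0]
            raise ValidationError(f"name {clash!r} used at both levels")
        object.__setattr__(self, "subtype_to_base", inv)
        object.__setattr__(self, "K_base", len(self.base_names))
        object.__setattr__(self, "K_sub", len(all_subs))

    # -- index maps ---------------------------------------------------------

    @property
    def subtype_names(self) -> tuple[str, ...]:
        """All subtypes in global index order."""
        return tuple(s for b in self.base_names for s in self.children[b])

    def base_index(self, name: str) -> int:
        try:
            return self.base_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown base type {name!r}") from None

    def subtype_index(self, name: str) -> int:
        try:
            return self.subtype_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown subtype {name!r}") from None

    def children_indices(self, base: int | str) -> np.ndarray:
        """Global subtype indices of one base's children (possibly empty)."""
        if isinstance(base, (int, np.integer)):
            base = self.base_names[int(base)]
        offset = 0
        for b in self.base_names:
            n = len(self.children[b])
            if b == base:
                return np.arange(offset, offset + n)
            offset += n
        raise ValidationError(f"unknown base type {base!r}")

    def is_terminal(self, base: int | str) -> bool:
        if isinstance(base, (int, np.integer)):
            base = self.base_names[int(base)]
        return len(self.children[base]) == 0

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict[str, list[str]]:
        return {b: list(self.children[b]) for b in self.base_names}

    def fingerprint(self) -> str:
        return sha256_of_text(canonical_json(self.to_dict()))

    def drop_subtypes(self, names: Sequence[str]) -> "CellTypeHierarchy":
        """Return a copy with the given subtypes removed (holdout training)."""
        for n in names:
            if n not in self.subtype_to_base:
                raise ValidationError(f"unknown subtype {n!r}")
        drop = set(names)
        return CellTypeHierarchy(
            base_names=self.base_names,
            children={b: tuple(s for s in self.children[b] if s not in drop)
                      for b in self.base_names},
        )

    def label_map_frame(self) -> pd.DataFrame:
        """Name/level/index table, exported alongside models for provenance."""
        rows = [(n, "base", i) for i, n in enumerate(self.base_names)]
        rows += [(n, "subtype", i) for i, n in enumerate(self.subtype_names)]
        return pd.DataFrame(rows, columns=["name", "level", "index"])


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def hierarchy_from_dict(mapping: Mapping[str, Sequence[str]]) -> CellTypeHierarchy:
    """Build and validate a hierarchy from ``{base: [subtypes...]}``."""
    for base, subs in mapping.items():
        if isinstance(subs, (str, bytes)) or not isinstance(subs, (list, tuple)):
            raise ValidationError(
                f"children of {base!r} must be a list of subtype names"
            )
        for s in subs:
            if not isinstance(s, str):
                raise ValidationError(
                    f"nested structures under {base!r} are not supported: "
                    "hierarchies are exactly two levels (base -> subtypes)"
                )
    return CellTypeHierarchy(
        base_names=tuple(mapping.keys()),
        children={b: tuple(mapping[b]) for b in mapping},
    )


def load_hierarchy(path: str | Path) -> CellTypeHierarchy:
    """Load a hierarchy from a JSON file ``{base: [subtypes...]}``.

    File order defines the index order at both levels, so a given file always
    yields the same encoding.
    """
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict):
        raise ValidationError(f"{path}: expected a JSON object of base -> subtype list")
    return hierarchy_from_dict(obj)


def save_hierarchy(hier: CellTypeHierarchy, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(hier.to_dict(), fh, indent=2)
        fh.write("\n")


def encode_labels(
    hier: CellTypeHierarchy,
    base_labels: Sequence[str],
    sub_labels: Sequence[str | None] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Map string labels to paired (base, subtype) index vectors.

    ``sub_labels`` may be ``None`` (no subtype information at all) or contain
    ``None``/NaN entries for individual cells; those cells receive the
    sentinel index.  A subtype that is not a child of its paired base label
    is an error, reported with the offending row.
    """
    base_idx = np.array([hier.base_index(b) for b in base_labels], dtype=np.int64)
    n = len(base_labels)
    sub_idx = np.full(n, NO_SUBTYPE, dtype=np.int64)
    if sub_labels is not None:
        if len(sub_labels) != n:
            raise ValidationError("base and subtype label lists differ in length")
        for row, (b, s) in enumerate(zip(base_labels, sub_labels)):
            if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
                continue
            if hier.subtype_to_base.get(s) != b:
                raise ValidationError(
                    f"row {row}: subtype {s!r} is not a child of base type {b!r}"
                )
            sub_idx[row] = hier.subtype_index(s)
    return base_idx, sub_idx


def decode_labels(
    hier: CellTypeHierarchy, base_idx: np.ndarray, sub_idx: np.ndarray
) -> tuple[list[str], list[str | None]]:
    """Inverse of :func:`encode_labels`; sentinel decodes to ``None``."""
    subs = hier.subtype_names
    base = [hier.base_names[int(i)] for i in base_idx]
    sub = [None if int(j) == NO_SUBTYPE else subs[int(j)] for j in sub_idx]
    return base, sub
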