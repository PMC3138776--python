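"""Ethnomedicinal use records, category vocabulary, and community matrices.

The analysis treats the set of taxa reported for one category of use (or for
one named condition such as malaria) as a "community" on the phylogeny.
This module ingests long-form use records or pre-built matrices, assigns the
13 canonical use categories, and produces the samples-by-taxa presence
matrix consumed by the signal and node-enrichment tests, plus the
descriptive tallies (uses per taxon/category, relative usage per region).

Presence is deliberately binary: a taxon either has a recorded use in a
category or it does not; report counts never weight the tests.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phylo import Phylogeny, normalize_label

__all__ = [
    "UseRecord",
    "CategoryVocabulary",
    "CANONICAL_CATEGORIES",
    "OVERALL_SAMPLE",
    "read_use_records",
    "assign_categories",
    "build_community_matrix",
    "read_wide_matrix",
    "read_phylocom_samples",
    "write_phylocom_samples",
    "apply_tip_mapping",
    "read_tip_mapping",
    "match_to_tree",
    "tally_uses",
    "relative_usage_by_region",
]

#: The 13 canonical categories of use. Fixed by default; synonym entries are
#: editable (see :class:`CategoryVocabulary`).
CANONICAL_CATEGORIES: tuple[str, ...] = (
    "Circulatory/Blood",
    "Gastro-intestinal",
    "Genito-urinary/Fertility",
    "Infections/Fever",
    "Inflammation",
    "Musculo-Skeletal",
    "Nervous",
    "Pain",
    "Poisons treatment",
    "Respiratory",
    "Sensory",
    "Skin",
    "Unspecific",
)

#: Name of the union-of-all-medicinal-taxa sample added to every matrix.
OVERALL_SAMPLE = "Medicinal uses overall"

_DEFAULT_SYNONYMS: dict[str, str] = {
    "infections/fevers": "Infections/Fever",
    "fever": "Infections/Fever",
    "fevers": "Infections/Fever",
    "infection": "Infections/Fever",
    "infections": "Infections/Fever",
    "gastrointestinal": "Gastro-intestinal",
    "gastro intestinal": "Gastro-intestinal",
    "musculoskeletal": "Musculo-Skeletal",
    "musculo skeletal": "Musculo-Skeletal",
    "genito-urinary": "Genito-urinary/Fertility",
    "genitourinary": "Genito-urinary/Fertility",
    "fertility": "Genito-urinary/Fertility",
    "circulatory": "Circulatory/Blood",
    "blood": "Circulatory/Blood",
    "poison": "Poisons treatment",
    "poisons": "Poisons treatment",
    "unspecified": "Unspecific",
}


class VocabularyError(ValueError):
    """Raised in strict mode when a category cannot be canonicalized."""


@dataclass(frozen=True)
class UseRecord:
    """One reported ethnomedicinal use of a taxon."""

    taxon: str
    category: str
    region: str = ""
    condition: str = ""
    source: str = ""

    def __post_init__(self):
        if not str(self.taxon).strip():
            raise ValueError("UseRecord.taxon must be nonempty")


@dataclass
class CategoryVocabulary:
    """Canonical category names plus case-insensitive synonyms.

    ``synonyms`` maps lowercase alternative spellings to canonical names;
    canonical names themselves always match case-insensitively.
    """

    categories: tuple[str, ...] = CANONICAL_CATEGORIES
    synonyms: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_SYNONYMS)
    )

    def __post_init__(self):
        self._canon = {c.lower(): c for c in self.categories}
        for syn, canon in self.synonyms.items():
            if canon not in self.categories:
                raise VocabularyError(
                    f"synonym {syn!r} maps to unknown category {canon!r}"
                )

    def canonicalize(self, name: str) -> Optional[str]:
        key = " ".join(str(name).strip().lower().split())
        return self._canon.get(key) or self.synonyms.get(key)

    @classmethod
    def from_tsv(cls, path) -> "CategoryVocabulary":
        """Load a two-column (synonym TAB canonical) table to extend defaults."""
        table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        syns = dict(_DEFAULT_SYNONYMS)
        for _, row in table.iterrows():
            syns[str(row.iloc[0]).strip().lower()] = str(row.iloc[1]).strip()
        return cls(synonyms=syns)


def read_use_records(source, sep: str = None) -> list[UseRecord]:
    """Read long-form use records from a delimited table (path or file-like).

    Requires at least ``taxon`` and ``category`` columns (case-insensitive);
    ``region``, ``condition`` and ``source`` are optional. The delimiter is
    sniffed from the header (tab, else comma) when not given.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    if not text.strip():
        warnings.warn("empty use-record table; returning no records", stacklevel=2)
        return []
    if sep is None:
        header = text.splitlines()[0]
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, comment="#").fillna("")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in ("taxon", "category") if c not in frame.columns]
    if missing:
        raise ValueError(
            "use-record table is missing mandatory columns: " + ", ".join(missing)
        )
    records = []
    for _, row in frame.iterrows():
        records.append(
            UseRecord(
                taxon=row["taxon"],
                category=row["category"],
                region=row.get("region", ""),
                condition=row.get("condition", ""),
                source=row.get("source", ""),
            )
        )
    return records


def assign_categories(
    records: Sequence[UseRecord],
    vocab: Optional[CategoryVocabulary] = None,
    strict: bool = False,
) -> list[UseRecord]:
    """Replace each record's category with its canonical form.

    Unmatched categories raise in strict mode; otherwise they pass through
    verbatim with a single summary warning.
    """
    vocab = vocab or CategoryVocabulary()
    out, unmatched = [], []
    for rec in records:
        canon = vocab.canonicalize(rec.category)
        if canon is None:
            unmatched.append(rec.category)
            out.append(rec)
        else:
            out.append(
                UseRecord(rec.taxon, canon, rec.region, rec.condition, rec.source)
            )
    if unmatched:
        msg = "categories without canonical match: " + ", ".join(
            sorted(set(unmatched))
        )
        if strict:
            raise VocabularyError(msg)
        warnings.warn(msg + " (kept verbatim)", stacklevel=2)
    return out


def _as_binary_frame(frame: pd.DataFrame) -> pd.DataFrame:
    values = frame.to_numpy()
    bad = ~np.isin(values, [0, 1])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary cell at taxon row {frame.index[i]!r}, "
            f"sample column {frame.columns[j]!r}: {values[i, j]!r}"
        )
    return frame.astype(int)


def build_community_matrix(
    records: Sequence[UseRecord],
    condition_samples: Optional[Sequence[str]] = None,
    add_overall: bool = True,
) -> pd.DataFrame:
    """Build the samples-by-taxa presence matrix from categorized records.

    One sample per category present in the records; one sample per requested
    condition (matched case-insensitively against the ``condition`` field);
    plus the union sample :data:`OVERALL_SAMPLE` covering every taxon with
    any medicinal record. Duplicate (taxon, category) rows collapse to a
    single presence, so the result is invariant under record duplication and
    reordering.
    """
    taxa = sorted({normalize_label(r.taxon) for r in records})
    samples: dict[str, set[str]] = {}
    for rec in records:
        samples.setdefault(rec.category, set()).add(normalize_label(rec.taxon))
    for cond in condition_samples or ():
        members = {
            normalize_label(r.taxon)
            for r in records
            if r.condition.strip().lower() == cond.strip().lower()
        }
        samples[cond] = members
    if add_overall:
        samples[OVERALL_SAMPLE] = {normalize_label(r.taxon) for r in records}
    names = sorted(samples)
    mat = pd.DataFrame(0, index=names, columns=taxa, dtype=int)
    for name, members in samples.items():
        for t in members:
            if t in mat.columns:
                mat.loc[name, t] = 1
    return mat


def read_wide_matrix(source) -> pd.DataFrame:
    """Read a wide 0/1 matrix: first column taxon, remaining columns samples.

    Returns the transposed (samples x taxa) presence matrix.
    """
    frame = pd.read_csv(source, sep="\t", index_col=0, comment="#")
    frame.index = [normalize_label(t) for t in frame.index]
    return _as_binary_frame(frame).T


def read_phylocom_samples(source) -> pd.DataFrame:
    """Read the 3-column Phylocom sample format (sample TAB abundance TAB taxon).

    Abundances collapse to presence — the analysis is presence-based.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    triples = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"malformed Phylocom sample line {lineno}: expected 3 "
                f"tab-separated fields, got {len(parts)}"
            )
        sample, abundance, taxon = parts
        try:
            float(abundance)
        except ValueError as exc:
            raise ValueError(
                f"malformed Phylocom sample line {lineno}: "
                f"non-numeric abundance {abundance!r}"
            ) from exc
        triples.append((sample.strip(), normalize_label(taxon)))
    if not triples:
        warnings.warn("empty Phylocom sample file", stacklevel=2)
        return pd.DataFrame(dtype=int)
    names = sorted({s for s, _ in triples})
    taxa = sorted({t for _, t in triples})
    mat = pd.DataFrame(0, index=names, columns=taxa, dtype=int)
    for s, t in triples:
        mat.loc[s, t] = 1
    return mat


def write_phylocom_samples(matrix: pd.DataFrame, target) -> None:
    """Write a presence matrix in the 3-column Phylocom sample format."""
    lines = []
    for sample in matrix.index:
        for taxon in matrix.columns[matrix.loc[sample].to_numpy() == 1]:
            lines.append(f"{sample}\t1\t{taxon}")
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(target, "write"):
        target.write(text)
    else:
        with open(target, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_tip_mapping(source) -> dict[str, list[str]]:
    """Read a species-to-tip mapping (two tab-separated columns, repeatable)."""
    mapping: dict[str, list[str]] = {}
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed mapping line {lineno}: {line!r}")
        mapping.setdefault(normalize_label(parts[0]), []).append(
            normalize_label(parts[1])
        )
    return mapping


def apply_tip_mapping(
    matrix: pd.DataFrame, mapping: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Expand species columns to accession tips.

    A species with several tree accessions propagates its presence to every
    mapped tip; unmapped columns pass through unchanged.
    """
    columns: dict[str, np.ndarray] = {}
    for taxon in matrix.columns:
        targets = mapping.get(taxon, [taxon])
        for tip in targets:
            prev = columns.get(tip, 0)
            columns[tip] = np.maximum(prev, matrix[taxon].to_numpy())
    out = pd.DataFrame(columns, index=matrix.index).astype(int)
    return out[sorted(out.columns)]


def match_to_tree(
    matrix: pd.DataFrame, tree: Phylogeny, prune_unmatched: bool = False
) -> pd.DataFrame:
    """Validate matrix taxa against tree tips.

    Unmatched taxa are an error by default; with ``prune_unmatched`` they are
    dropped with a warning (counts logged in the message).
    """
    cols = [normalize_label(c) for c in matrix.columns]
    matrix = matrix.copy()
    matrix.columns = cols
    unmatched = [c for c in cols if not tree.has_tip(c)]
    if unmatched:
        msg = (
            f"{len(unmatched)} of {len(cols)} matrix taxa not found in tree: "
            + ", ".join(sorted(unmatched))
        )
        if not prune_unmatched:
            raise ValueError(msg)
        warnings.warn(msg + " (dropped)", stacklevel=2)
        matrix = matrix.drop(columns=unmatched)
    return matrix


def tally_uses(records: Sequence[UseRecord], by: str = "taxon") -> pd.Series:
    """Count use records grouped by ``taxon``, ``category`` or ``region``."""
    if by not in ("taxon", "category", "region"):
        raise ValueError(f"cannot tally by {by!r}")
    if not records:
        raise ValueError("tally_uses requires at least one record")
    keys = [getattr(r, by) for r in records]
    counts = pd.Series(keys).value_counts().sort_index()
    counts.index.name = by
    counts.name = "n_uses"
    return counts.sort_values(ascending=False, kind="stable")


def relative_usage_by_region(records: Sequence[UseRecord]) -> pd.DataFrame:
    """Per-region proportions of uses falling in each category (rows sum to 1)."""
    rows = [(r.region.strip(), r.category) for r in records if r.region.strip()]
    dropped = len(records) - len(rows)
    if dropped:
        warnings.warn(
            f"{dropped} record(s) without a region omitted from proportions",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no records carry a region")
    frame = pd.DataFrame(rows, columns=["region", "category"])
    counts = frame.value_counts().unstack(fill_value=0).sort_index()
    counts = counts[sorted(counts.columns)]
    return counts.div(counts.sum(axis=1), axis=0)
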