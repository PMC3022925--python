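"""Overlapping physicochemical amino-acid property classes.

Residues carry sets of labels (a serine is simultaneously polar, hydroxylic,
small and tiny), so column profiles over an alignment are per-label fractions
that need not sum to one. The packaged default scheme is a Taylor-style
overlapping classification shipped as a TSV data file and overridable at
load time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .errors import EmptyColumnError, RangeError, ValidationError
from .io_formats import HomologAlignmentSet

PROPERTY_LABELS = frozenset({
    "polar", "non-polar", "hydrophobic", "hydrophilic", "hydroxylic",
    "charged", "positive", "negative", "aliphatic", "aromatic",
    "small", "tiny", "sulphur-containing", "amidic",
})

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PropertyScheme:
    """Mapping residue -> frozenset of property labels.

    Every standard residue must carry at least one label; the stop symbol '*'
    carries none; polar and non-polar are mutually exclusive per residue.
    """

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.mapping)
        if missing:
            raise ValidationError(
                f"scheme lacks residues {sorted(missing)!r}"
            )
        for res, labels in self.mapping.items():
            bad = set(labels) - PROPERTY_LABELS
            if bad:
                raise ValidationError(
                    f"residue {res!r}: unknown labels {sorted(bad)!r}"
                )
            if res in STANDARD_RESIDUES and not labels:
                raise ValidationError(f"residue {res!r}: empty label set")
            if {"polar", "non-polar"} <= set(labels):
                raise ValidationError(
                    f"residue {res!r}: polar and non-polar are exclusive"
                )
        if self.mapping.get("*"):
            raise ValidationError("'*' must carry no labels")

    def labels(self, residue: str) -> frozenset[str]:
        residue = residue.upper()
        if residue not in self.mapping:
            raise ValidationError(f"residue {residue!r} not in scheme")
        return frozenset(self.mapping[residue])


@dataclass(frozen=True)
class PropertyChange:
    """Set-algebra of labels between a reference and a variant residue."""

    ref_labels: frozenset[str]
    alt_labels: frozenset[str]

    @property
    def gained(self) -> frozenset[str]:
        return self.alt_labels - self.ref_labels

    @property
    def lost(self) -> frozenset[str]:
        return self.ref_labels - self.alt_labels

    @property
    def shared(self) -> frozenset[str]:
        return self.ref_labels & self.alt_labels


def load_scheme(path: str | os.PathLike | None = None) -> PropertyScheme:
    """Load a property scheme TSV (residue<TAB>comma-separated labels).

    With no path, the packaged default scheme is used.
    """
    if path is None:
        text = (
            resources.files("snpchar") / "data" / "aa_properties.tsv"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    mapping: dict[str, frozenset[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        res = parts[0].upper()
        labels = (
            frozenset(l for l in parts[1].split(",") if l)
            if len(parts) > 1 else frozenset()
        )
        mapping[res] = labels
    mapping.setdefault("*", frozenset())
    return PropertyScheme(mapping)


_DEFAULT: PropertyScheme | None = None


def default_scheme() -> PropertyScheme:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_scheme()
    return _DEFAULT


def property_change(
    ref_aa: str, alt_aa: str, scheme: PropertyScheme | None = None
) -> PropertyChange:
    """Characterize the label change between reference and variant residues."""
    scheme = scheme or default_scheme()
    return PropertyChange(scheme.labels(ref_aa), scheme.labels(alt_aa))


def column_property_frequencies(
    alignment: HomologAlignmentSet,
    column: int,
    scheme: PropertyScheme | None = None,
    exclude_reference: bool = True,
) -> dict[str, float]:
    """Per-label residue fractions at a 1-based aligned column.

    Gapped rows are excluded from the denominator; by default the reference
    row is excluded too, so fractions describe the homologues. Labels carried
    by no counted residue report 0.0; overlapping labels mean the values need
    not sum to 1.
    """
    scheme = scheme or default_scheme()
    if not 1 <= column <= alignment.aligned_length:
        raise RangeError(
            f"column {column} outside aligned length "
            f"{alignment.aligned_length}"
        )
    if exclude_reference:
        residues = [row[column - 1] for _, row in alignment.homolog_rows()]
    else:
        residues = [row[column - 1] for row in alignment.rows]
    residues = [r for r in residues if r != "-"]
    if not residues:
        raise EmptyColumnError(
            f"alignment {alignment.gene_id!r}: column {column} entirely "
            "gapped among counted rows"
        )
    n = len(residues)
    freqs = {label: 0.0 for label in PROPERTY_LABELS}
    for res in residues:
        for label in scheme.labels(res):
            freqs[label] += 1.0
    return {label: count / n for label, count in freqs.items()}


def write_property_table(
    rows: Mapping[tuple[str, int], Mapping[str, float]],
    path: str | os.PathLike,
) -> None:
    """Write per-site label fractions as a long-format table.

    ``rows`` maps (gene_id, position) to a label->fraction mapping; output
    columns are ``gene_id position label fraction``, labels sorted.
    """
    with open(path, "w") as fh:
        fh.write("gene_id\tposition\tlabel\tfraction\n")
        for (gene_id, position), freqs in rows.items():
            for label in sorted(freqs):
                fh.write(
                    f"{gene_id}\t{position}\t{label}\t{freqs[label]:.6g}\n"
                )
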