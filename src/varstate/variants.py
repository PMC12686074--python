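"""Proteins, missense variants and saturation-mutagenesis enumeration.

The variant space of a protein of length ``L`` under single-residue
substitution is the set of all ``19 * L`` (position, ref, alt) triples with
``alt != ref`` over the 20 canonical amino acids.  Variants are written in
short HGVS-p form, e.g. ``p.V464M``.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_LABEL_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


class VariantFormatError(ValueError):
    """Raised for malformed sequences, labels or inconsistent variants."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein identified by ``id`` with one-letter ``residues``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        for i, aa in enumerate(self.residues, start=1):
            if aa not in _AA_SET:
                raise VariantFormatError(
                    f"non-canonical residue {aa!r} at position {i} in {self.id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Variant:
    """A single-residue substitution, 1-based on the canonical sequence."""

    position: int
    ref_aa: str
    alt_aa: str
    gnomad_reported: Optional[bool] = None
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantFormatError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in _AA_SET or self.alt_aa not in _AA_SET:
            raise VariantFormatError(
                f"non-canonical amino acid in {self.ref_aa}{self.position}{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise VariantFormatError(
                f"synonymous substitution {self.ref_aa}{self.position}{self.alt_aa}"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise VariantFormatError(f"MAF must be in [0, 1], got {self.maf}")

    @property
    def label(self) -> str:
        """Canonical short HGVS-p form, e.g. ``p.V464M``."""
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def load_fasta(path: str | Path) -> ProteinSequence:
    """Read the first record of a FASTA file as a :class:`ProteinSequence`.

    Residues are uppercased; any character outside the 20 canonical
    one-letter codes raises :class:`VariantFormatError` naming its position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise VariantFormatError(f"no FASTA records in {path}")
    rec = records[0]
    return ProteinSequence(id=rec.id, residues=str(rec.seq).upper())


def parse_variant_label(
    label: str, protein: Optional[ProteinSequence] = None
) -> Variant:
    """Parse a short HGVS-p label such as ``p.V464M`` (the ``p.`` is optional).

    If ``protein`` is given, the reference amino acid and position are
    validated against the sequence.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise VariantFormatError(f"malformed variant label {label!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if ref == alt:
        raise VariantFormatError(f"synonymous label {label!r}")
    v = Variant(position=pos, ref_aa=ref, alt_aa=alt)
    if protein is not None:
        if pos > protein.length:
            raise VariantFormatError(
                f"{label!r}: position {pos} exceeds protein length {protein.length}"
            )
        if protein.residues[pos - 1] != ref:
            raise VariantFormatError(
                f"{label!r}: reference {ref} does not match sequence "
                f"residue {protein.residues[pos - 1]} at {pos}"
            )
    return v


@dataclass
class VariantSet:
    """An ordered, duplicate-free collection of variants on one protein."""

    protein: ProteinSequence
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[int, str, str]] = set()
        for v in self.variants:
            if v.position > self.protein.length:
                raise VariantFormatError(
                    f"{v.label}: position beyond protein length {self.protein.length}"
                )
            if self.protein.residues[v.position - 1] != v.ref_aa:
                raise VariantFormatError(
                    f"{v.label}: reference mismatch with sequence residue "
                    f"{self.protein.residues[v.position - 1]}"
                )
            if v.key in seen:
                raise VariantFormatError(f"duplicate variant {v.label}")
            seen.add(v.key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.variants]


def enumerate_saturation(protein: ProteinSequence) -> VariantSet:
    """Enumerate all single-residue substitutions of ``protein``.

    Every position is substituted with each of the 19 alternative amino
    acids, yielding exactly ``19 * L`` variants in deterministic order
    (position ascending, alternate amino acid alphabetical).
    """
    if protein.length == 0:
        raise VariantFormatError("cannot enumerate an empty sequence")
    out: list[Variant] = []
    for pos, ref in enumerate(protein.residues, start=1):
        for alt in AMINO_ACIDS:
            if alt != ref:
                out.append(Variant(position=pos, ref_aa=ref, alt_aa=alt))
    return VariantSet(protein=protein, variants=tuple(out))


@dataclass
class DomainMap:
    """Ordered, non-overlapping 1-based inclusive intervals with labels."""

    intervals: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals))
        prev_end = 0
        for start, end, lab in ivs:
            if start < 1 or end < start:
                raise VariantFormatError(f"bad interval [{start}, {end}] ({lab})")
            if start <= prev_end:
                raise VariantFormatError(
                    f"overlapping domain intervals near [{start}, {end}] ({lab})"
                )
            prev_end = end
        self.intervals = ivs

    def lookup(self, position: int) -> str:
        for start, end, lab in self.intervals:
            if start <= position <= end:
                return lab
        return "linker"


#: Illustrative JAK1 domain boundaries (approximate, for display only; domain
#: coordinates are configuration the user should supply for real analyses).
DEFAULT_JAK1_DOMAINS = DomainMap(
    intervals=(
        (34, 420, "FERM"),
        (439, 544, "SH2"),
        (583, 855, "PK"),
        (875, 1153, "TK"),
    )
)


def annotate_domain(variant: Variant, domain_map: DomainMap) -> str:
    """Label of the domain interval containing the variant, else ``"linker"``."""
    return domain_map.lookup(variant.position)


def read_variant_list(path: str | Path) -> list[str]:
    """Read variant labels from a plain list (one per line) or a TSV with a
    ``variant`` column."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()
    if not first:
        return []
    if "\t" in first[0] or first[0].strip().lower() == "variant":
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        if "variant" not in cols:
            raise VariantFormatError(f"no 'variant' column in {path}")
        return [str(x) for x in df[cols["variant"]]]
    return [line.strip() for line in first if line.strip()]


def variants_to_frame(
    vset: VariantSet, domain_map: Optional[DomainMap] = None
) -> pd.DataFrame:
    """Tabulate a variant set (columns: variant, position, ref_aa, alt_aa,
    domain when a map is given)."""
    data = {
        "variant": [v.label for v in vset],
        "position": [v.position for v in vset],
        "ref_aa": [v.ref_aa for v in vset],
        "alt_aa": [v.alt_aa for v in vset],
    }
    if domain_map is not None:
        data["domain"] = [annotate_domain(v, domain_map) for v in vset]
    return pd.DataFrame(data)


def write_variants_tsv(
    vset: VariantSet, path: str | Path, domain_map: Optional[DomainMap] = None
) -> None:
    variants_to_frame(vset, domain_map).to_csv(path, sep="\t", index=False)
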