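"""Protein GO annotations (GAF) and structure-to-protein mapping.

Only molecular-function annotations survive parsing: the quality scores
compare protein *functions*, and process/component terms relate to
structure too indirectly to be informative.  Annotation subjects are
typically UniProt accessions; structures (PDB chains) are joined to them
through a two-column mapping table.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.UniProt.GOA import GAF20FIELDS

from .ontology import GODag, UnknownTermError

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Direct molecular-function GO annotations per subject.

    ``provenance`` records the evidence code of each (subject, term) pair;
    term ids are primary (alt_ids already resolved).
    """

    terms_by_subject: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, subject: str, term: str, evidence: str = "") -> None:
        self.terms_by_subject.setdefault(subject, set()).add(term)
        self.provenance[(subject, term)] = evidence

    def terms(self, subject: str) -> frozenset[str]:
        return frozenset(self.terms_by_subject.get(subject, ()))

    def subjects(self) -> list[str]:
        return sorted(self.terms_by_subject)

    def __len__(self) -> int:
        return len(self.terms_by_subject)


def _as_stream(source):
    if isinstance(source, str) and "\n" in source:
        return io.StringIO(source)
    if isinstance(source, str):
        return open(source)
    return source


def parse_gaf(
    source,
    dag: GODag,
    evidence_filter: set[str] | None = None,
) -> AnnotationSet:
    """Read a GAF 2.x file, keeping molecular-function rows only.

    Rows with a NOT qualifier are dropped (they assert absence of function);
    term accessions are resolved through ``dag`` so alt_ids collapse onto
    primary ids.  ``evidence_filter`` optionally restricts evidence codes
    (by default everything, including IEA, is accepted).  Malformed rows are
    skipped with a logged line number; an input yielding no usable rows is
    an error.
    """
    annset = AnnotationSet()
    stream = _as_stream(source)
    n_rows = 0
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 15:
            logger.warning("skipping malformed GAF row at line %d", lineno)
            continue
        row = dict(zip(GAF20FIELDS, fields))
        n_rows += 1
        if "NOT" in row["Qualifier"].split("|"):
            continue
        if row["Aspect"] != "F":
            continue
        if evidence_filter is not None and row["Evidence"] not in evidence_filter:
            continue
        try:
            term = dag.resolve(row["GO_ID"])
        except UnknownTermError:
            logger.warning(
                "skipping unknown GO term %s at line %d", row["GO_ID"], lineno
            )
            continue
        annset.add(row["DB_Object_ID"], term, row["Evidence"])
    if n_rows == 0:
        raise AnnotationError("no usable annotation rows in GAF input")
    return annset


def write_gaf(annset: AnnotationSet, stream) -> None:
    """Write an AnnotationSet as minimal GAF 2.0 rows (MF aspect)."""
    stream.write("!gaf-version: 2.0\n")
    for subject in annset.subjects():
        for term in sorted(annset.terms_by_subject[subject]):
            evidence = annset.provenance.get((subject, term), "IEA")
            row = [""] * len(GAF20FIELDS)
            row[GAF20FIELDS.index("DB")] = "UniProtKB"
            row[GAF20FIELDS.index("DB_Object_ID")] = subject
            row[GAF20FIELDS.index("DB_Object_Symbol")] = subject
            row[GAF20FIELDS.index("GO_ID")] = term
            row[GAF20FIELDS.index("DB:Reference")] = "GO_REF:0000000"
            row[GAF20FIELDS.index("Evidence")] = evidence
            row[GAF20FIELDS.index("Aspect")] = "F"
            row[GAF20FIELDS.index("DB_Object_Type")] = "protein"
            row[GAF20FIELDS.index("Taxon_ID")] = "taxon:0"
            row[GAF20FIELDS.index("Date")] = "20120501"
            row[GAF20FIELDS.index("Assigned_By")] = "goqa"
            stream.write("\t".join(row) + "\n")


def normalize_structure_id(structure_id: str) -> str:
    """Normalise a PDB-chain identifier to ``<pdb lower>-<CHAIN upper>``.

    Accepts ``1xyzA``, ``1xyz_A``, ``1XYZ-a`` and similar DALI dialects.
    Identifiers that do not look like a 4-character PDB id plus a chain are
    lower-cased as-is.
    """
    raw = structure_id.strip()
    for sep in ("-", "_", ":"):
        if sep in raw:
            pdb, _, chain = raw.partition(sep)
            if len(pdb) == 4 and chain:
                return f"{pdb.lower()}-{chain.upper()}"
    if len(raw) == 5 and raw[:4].isalnum():
        return f"{raw[:4].lower()}-{raw[4].upper()}"
    return raw.lower()


@dataclass
class StructureAnnotationIndex:
    """Mapping from normalised structure ids to annotation subject ids."""

    subjects_by_structure: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def lookup(self, structure_id: str) -> tuple[str, ...]:
        """Subjects mapped to a structure; empty tuple means unannotated."""
        return self.subjects_by_structure.get(normalize_structure_id(structure_id), ())

    def annotation_terms(self, structure_id: str, annset: AnnotationSet) -> frozenset[str]:
        """Union of the MF terms of every subject mapped to the structure."""
        terms: set[str] = set()
        for subject in self.lookup(structure_id):
            terms |= annset.terms(subject)
        return frozenset(terms)

    def __len__(self) -> int:
        return len(self.subjects_by_structure)


def load_structure_index(source) -> StructureAnnotationIndex:
    """Load a two-column TSV of (structure id, annotation subject id).

    Duplicate structure keys accumulate: a chain mapped to several subjects
    has the subjects' term sets unioned at lookup time.
    """
    stream = _as_stream(source)
    mapping: dict[str, list[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise AnnotationError(f"mapping line {lineno} needs two columns: {line!r}")
        key = normalize_structure_id(parts[0])
        subjects = mapping.setdefault(key, [])
        if parts[1] not in subjects:
            subjects.append(parts[1])
    if not mapping:
        raise AnnotationError("empty structure-to-annotation mapping")
    return StructureAnnotationIndex(
        {key: tuple(vals) for key, vals in mapping.items()}
    )


def write_structure_index(index: StructureAnnotationIndex, stream) -> None:
    for structure in sorted(index.subjects_by_structure):
        for subject in index.subjects_by_structure[structure]:
            stream.write(f"{structure}\t{subject}\n")
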