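"""Structural-neighbor lists and Slist construction.

Structural comparison is delegated entirely to DALI: neighbors enter as
(chain id, Z-score) pairs, either from DALI summary text (the "pdb90"
listing) or from a plain two-column table.  The Slist — one record per
neighbor carrying its Z-score and its functional similarity (FS) to the
prediction target — is the sole input to every quality score.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .annotations import AnnotationSet, StructureAnnotationIndex, normalize_structure_id
from .ontology import GODag, SemanticWeights, DEFAULT_WEIGHTS, functional_similarity

logger = logging.getLogger(__name__)

#: DALI hit row: "  1:  1xyz-A 35.6  2.1  140  150  38 ..."
_DALI_ROW = re.compile(r"^\s*\d+:\s+(\S+)\s+(-?\d+(?:\.\d+)?)\s")


class NeighborParseError(ValueError):
    pass


@dataclass(frozen=True)
class StructuralNeighbor:
    neighbor_id: str
    z_score: float


@dataclass(frozen=True)
class SlistRecord:
    neighbor_id: str
    z_score: float
    fs: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fs <= 1.0:
            raise ValueError(f"FS out of [0, 1]: {self.fs}")


@dataclass(frozen=True)
class Slist:
    """Per-model similarity list, sorted by descending Z-score.

    Ties on Z are broken by neighbor id ascending so the ranking that the
    ROC-style scores scan is a deterministic total order.
    """

    model_id: str
    records: tuple[SlistRecord, ...]
    n_input_neighbors: int = 0
    n_unannotated: int = 0

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.records, key=lambda r: (-r.z_score, r.neighbor_id))
        )
        object.__setattr__(self, "records", ordered)

    def __len__(self) -> int:
        return len(self.records)


def parse_dali_output(source, query_id: str | None = None) -> list[StructuralNeighbor]:
    """Extract (chain, Z) pairs from DALI summary text.

    Hit rows look like ``  1:  1xyz-A 35.6  2.1  140 ...``.  If ``query_id``
    is given, self-hits against the query chain are removed.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    elif isinstance(source, str):
        source = open(source)
    query_norm = normalize_structure_id(query_id) if query_id else None
    hits: list[StructuralNeighbor] = []
    for line in source:
        match = _DALI_ROW.match(line)
        if match is None:
            continue
        neighbor_id, z_text = match.groups()
        if query_norm and normalize_structure_id(neighbor_id) == query_norm:
            continue
        hits.append(StructuralNeighbor(neighbor_id, float(z_text)))
    if not hits:
        raise NeighborParseError("no parseable DALI hit rows found")
    return hits


def parse_neighbor_tsv(source) -> list[StructuralNeighbor]:
    """Read a two-column (neighbor id, Z-score) table; a header is skipped."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    elif isinstance(source, str):
        source = open(source)
    hits: list[StructuralNeighbor] = []
    for lineno, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise NeighborParseError(f"line {lineno}: expected two columns")
        try:
            z = float(parts[1])
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise NeighborParseError(
                f"line {lineno}: non-numeric Z-score {parts[1]!r}"
            ) from None
        hits.append(StructuralNeighbor(parts[0], z))
    if not hits:
        raise NeighborParseError("no neighbor rows found")
    return hits


def _deduplicate(neighbors: Iterable[StructuralNeighbor]) -> list[StructuralNeighbor]:
    """Collapse repeated chains, keeping each chain's highest Z-score."""
    best: dict[str, StructuralNeighbor] = {}
    for hit in neighbors:
        key = normalize_structure_id(hit.neighbor_id)
        kept = best.get(key)
        if kept is None or hit.z_score > kept.z_score:
            best[key] = StructuralNeighbor(key, hit.z_score)
    return list(best.values())


def build_slist(
    model_id: str,
    neighbors: Sequence[StructuralNeighbor],
    target_terms: Iterable[str],
    dag: GODag,
    annset: AnnotationSet,
    index: StructureAnnotationIndex,
    policy: Literal["drop", "zero_fs"] = "drop",
    weights: SemanticWeights = DEFAULT_WEIGHTS,
) -> Slist:
    """Attach an FS score to every neighbor and assemble the Slist.

    Each neighbor chain is resolved to its annotation subject(s) through
    ``index``; the subjects' molecular-function terms are unioned and
    compared with ``target_terms`` by best-match-average Wang similarity.
    Neighbors with no annotation are dropped (default) or kept with FS = 0
    (``policy="zero_fs"``); either way the count is recorded.
    """
    target = sorted({dag.resolve(t) for t in target_terms})
    if not target:
        raise ValueError(
            "target term set is empty; the method requires an annotated target"
        )
    deduped = _deduplicate(neighbors)
    records: list[SlistRecord] = []
    n_unannotated = 0
    for hit in deduped:
        terms = index.annotation_terms(hit.neighbor_id, annset)
        if not terms:
            n_unannotated += 1
            if policy == "drop":
                continue
            records.append(SlistRecord(hit.neighbor_id, hit.z_score, 0.0))
            continue
        fs = functional_similarity(dag, target, terms, weights)
        records.append(SlistRecord(hit.neighbor_id, hit.z_score, fs))
    if n_unannotated:
        logger.info(
            "%s: %d/%d neighbors unannotated (policy=%s)",
            model_id, n_unannotated, len(deduped), policy,
        )
    return Slist(
        model_id=model_id,
        records=tuple(records),
        n_input_neighbors=len(deduped),
        n_unannotated=n_unannotated,
    )


def count_significant(slist: Slist, z_min: float = 2.0) -> int:
    """Number of records with Z-score >= ``z_min`` (inclusive)."""
    return sum(1 for r in slist.records if r.z_score >= z_min)


def write_slist(slist: Slist, stream) -> None:
    stream.write("model_id\tneighbor_id\tz_score\tfs\n")
    for r in slist.records:
        stream.write(f"{slist.model_id}\t{r.neighbor_id}\t{r.z_score:.6g}\t{r.fs:.10g}\n")


def read_slist(source) -> Slist:
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    elif isinstance(source, str):
        source = open(source)
    records = []
    model_id = ""
    for lineno, line in enumerate(source, start=1):
        if lineno == 1 or not line.strip():
            continue
        model_id, neighbor_id, z, fs = line.split("\t")
        records.append(SlistRecord(neighbor_id, float(z), float(fs)))
    return Slist(model_id=model_id, records=tuple(records),
                 n_input_neighbors=len(records))
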