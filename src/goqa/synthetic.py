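"""Seeded generators for toy ontologies, annotations and model ensembles.

Real inputs to the scoring pipeline are large downloads (the Gene
Ontology, GOA, a DALI search of the PDB).  These generators produce small
synthetic stand-ins with the same structure so every stage is exercisable
and testable offline:

* a toy molecular-function DAG grown term by term (acyclic by
  construction),
* random annotation sets over that DAG,
* a model ensemble with a latent quality q per model in [0, 1] that
  drives, jointly, (i) how enriched the model's structural neighborhood is
  in functionally similar proteins, (ii) how high those neighbors' Z-scores
  reach, and (iii) the observed GDT-TS.  High-q models thus concentrate
  neighbors in the high-Z/high-FS region, while low-q models populate the
  low-Z and/or low-FS regions — the regimes in which a prediction has
  failed, resembles function without structure, or structure without
  function.

Everything is driven by ``numpy.random.default_rng`` under a mandatory
seed and is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotations import AnnotationSet
from .neighbors import Slist, SlistRecord
from .ontology import GODag, GOTerm

NAMESPACE = "molecular_function"


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def generate_toy_dag(
    n_terms: int,
    p_part_of: float = 0.2,
    max_parents: int = 2,
    seed: int = 0,
) -> GODag:
    """Grow a random single-namespace DAG of ``n_terms`` terms.

    Terms are added in topological order; each new term attaches to one to
    ``max_parents`` existing terms, each edge being ``part_of`` with
    probability ``p_part_of`` and ``is_a`` otherwise.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    terms: dict[str, GOTerm] = {
        _term_id(0): GOTerm(_term_id(0), "term_0000001 root", NAMESPACE)
    }
    for i in range(1, n_terms):
        n_parents = int(rng.integers(1, max_parents + 1))
        parent_idx = rng.choice(i, size=min(n_parents, i), replace=False)
        parents = tuple(
            (_term_id(int(j)), "part_of" if rng.random() < p_part_of else "is_a")
            for j in sorted(parent_idx)
        )
        tid = _term_id(i)
        terms[tid] = GOTerm(tid, f"term_{i + 1:07d}", NAMESPACE, parents=parents)
    return GODag(terms)


def generate_annotations(
    dag: GODag,
    n_proteins: int,
    terms_per_protein: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> AnnotationSet:
    """Annotate ``n_proteins`` synthetic subjects with random non-root terms."""
    rng = np.random.default_rng(seed)
    candidates = sorted(t for t in dag.terms if dag.terms[t].parents)
    if not candidates:  # single-root DAG
        candidates = sorted(dag.terms)
    lo, hi = terms_per_protein
    annset = AnnotationSet()
    for i in range(n_proteins):
        subject = f"SYN{i + 1:05d}"
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(candidates), size=min(k, len(candidates)), replace=False)
        for j in sorted(chosen):
            annset.add(subject, candidates[int(j)], "IEA")
    return annset


@dataclass(frozen=True)
class EnsembleParams:
    """Study conditions for a synthetic model ensemble.

    A neighbor of a model is "functional" (drawn from the
    functionally-similar population) with probability
    ``functional_base_prob + functional_gain * q``; this same functional
    coherence also scales how far the functional neighbors' Z-scores reach
    above the significance floor.  FS values are Beta-distributed with a
    high-mode shape for functional neighbors and a low-mode shape for
    background ones, mimicking the empirical separation of functionally
    related vs unrelated structural neighbors around FS ~ 0.6.
    """

    n_models: int = 200
    neighbors_per_model: int = 60
    functional_base_prob: float = 0.15
    functional_gain: float = 0.5
    z_scale: float = 30.0
    fs_shapes: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 2.0), (2.0, 8.0))
    gdt_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.functional_base_prob <= 1.0:
            raise ValueError("functional_base_prob must be in [0, 1]")
        if not 0.0 <= self.functional_gain <= 1.0:
            raise ValueError("functional_gain must be in [0, 1]")
        if self.z_scale <= 0 or self.gdt_noise_sd < 0:
            raise ValueError("scales must be positive")


@dataclass(frozen=True)
class SyntheticEnsemble:
    """Per-model Slists plus the latent quality and derived GDT-TS table."""

    slists: tuple[Slist, ...]
    quality: Mapping[str, float]
    gdt: Mapping[str, float]


def _model_name(i: int, target: str = "T0001") -> str:
    return f"{target}TS{(i // 5) + 1:03d}_{(i % 5) + 1}"


def generate_ensemble(params: EnsembleParams) -> SyntheticEnsemble:
    """Draw a seeded model ensemble under ``params``.

    Per model: q ~ U(0,1); each neighbor is functional with probability
    p(q) = base + gain*q, drawing FS ~ Beta(fs_shapes[0]) and
    Z = 2 + z_scale * p(q) * U(0,1); background neighbors draw
    FS ~ Beta(fs_shapes[1]) and Z = 2 + 6 * U(0,1).  Observed quality is
    GDT = clip(100 * (0.15 + 0.7 q) + N(0, gdt_noise_sd), 0, 100).
    """
    rng = np.random.default_rng(params.seed)
    (a_fun, b_fun), (a_bg, b_bg) = params.fs_shapes
    slists: list[Slist] = []
    quality: dict[str, float] = {}
    gdt: dict[str, float] = {}
    for i in range(params.n_models):
        model = _model_name(i)
        q = float(rng.uniform())
        p_fun = min(1.0, params.functional_base_prob + params.functional_gain * q)
        records = []
        for j in range(params.neighbors_per_model):
            if rng.random() < p_fun:
                fs = float(rng.beta(a_fun, b_fun))
                z = 2.0 + params.z_scale * p_fun * float(rng.uniform())
            else:
                fs = float(rng.beta(a_bg, b_bg))
                z = 2.0 + 6.0 * float(rng.uniform())
            records.append(SlistRecord(f"nb{j + 1:04d}-A", z, fs))
        slists.append(
            Slist(model_id=model, records=tuple(records),
                  n_input_neighbors=len(records))
        )
        quality[model] = q
        gdt[model] = float(
            np.clip(100.0 * (0.15 + 0.7 * q) + rng.normal(0.0, params.gdt_noise_sd),
                    0.0, 100.0)
        )
    return SyntheticEnsemble(tuple(slists), quality, gdt)


def write_fixture(
    outdir,
    n_targets: int = 2,
    models_per_target: int = 10,
    n_terms: int = 40,
    n_background_subjects: int = 20,
    n_functional_subjects: int = 10,
    params: EnsembleParams | None = None,
) -> None:
    """Write a complete, mutually consistent file fixture to ``outdir``.

    Produces everything the scoring pipeline reads from disk: a toy OBO
    ontology, a GAF annotation file over synthetic subjects, a structure
    to subject mapping, per-model neighbor TSVs (``neighbors/<model>.tsv``),
    a target term list (``targets.tsv``), a model-to-target grouping
    (``model_targets.tsv``) and a GDT-TS table.  Functional neighbors are
    subjects annotated with the target's own terms, so the FS scores
    recomputed from the ontology at scoring time separate the two neighbor
    populations just as the in-memory ensemble generator does.
    """
    from pathlib import Path

    from .annotations import write_gaf
    from .evaluation import write_gdt_table
    from .ontology import write_obo

    if params is None:
        params = EnsembleParams()
    rng = np.random.default_rng(params.seed)
    outdir = Path(outdir)
    (outdir / "neighbors").mkdir(parents=True, exist_ok=True)

    dag = generate_toy_dag(n_terms, seed=int(rng.integers(2**31)))
    non_root = sorted(t for t in dag.terms if dag.terms[t].parents)

    annset = AnnotationSet()
    mapping_lines: list[str] = []
    target_terms: dict[str, list[str]] = {}
    pools: dict[str, tuple[list[str], list[str]]] = {}
    structure_counter = 0

    def new_structure(subject: str) -> str:
        nonlocal structure_counter
        structure_counter += 1
        sid = f"s{structure_counter:03d}-A"
        mapping_lines.append(f"{sid}\t{subject}")
        return sid

    for t in range(1, n_targets + 1):
        target = f"T{t:04d}"
        chosen = rng.choice(len(non_root), size=2, replace=False)
        terms = [non_root[int(j)] for j in sorted(chosen)]
        target_terms[target] = terms
        functional: list[str] = []
        for k in range(n_functional_subjects):
            subject = f"FUN{t:02d}{k + 1:03d}"
            for term in terms:
                annset.add(subject, term, "IEA")
            functional.append(new_structure(subject))
        background: list[str] = []
        for k in range(n_background_subjects):
            subject = f"BKG{t:02d}{k + 1:03d}"
            n_ann = int(rng.integers(1, 4))
            chosen_bg = rng.choice(len(non_root), size=n_ann, replace=False)
            for j in sorted(chosen_bg):
                annset.add(subject, non_root[int(j)], "IEA")
            background.append(new_structure(subject))
        pools[target] = (functional, background)

    gdt: dict[str, float] = {}
    grouping_lines: list[str] = []
    for target in sorted(target_terms):
        functional, background = pools[target]
        for m in range(1, models_per_target + 1):
            model = f"{target}TS{m:03d}_1"
            grouping_lines.append(f"{model}\t{target}")
            q = float(rng.uniform())
            p_fun = min(1.0, params.functional_base_prob + params.functional_gain * q)
            rows = ["neighbor_id\tz_score"]
            for _ in range(params.neighbors_per_model):
                if rng.random() < p_fun:
                    sid = functional[int(rng.integers(len(functional)))]
                    z = 2.0 + params.z_scale * p_fun * float(rng.uniform())
                else:
                    sid = background[int(rng.integers(len(background)))]
                    z = 2.0 + 6.0 * float(rng.uniform())
                rows.append(f"{sid}\t{z:.4f}")
            (outdir / "neighbors" / f"{model}.tsv").write_text("\n".join(rows) + "\n")
            gdt[model] = float(
                np.clip(100.0 * (0.15 + 0.7 * q) + rng.normal(0.0, params.gdt_noise_sd),
                        0.0, 100.0)
            )

    with open(outdir / "ontology.obo", "w") as fh:
        write_obo(dag, fh)
    with open(outdir / "annotations.gaf", "w") as fh:
        write_gaf(annset, fh)
    (outdir / "mapping.tsv").write_text("\n".join(mapping_lines) + "\n")
    (outdir / "targets.tsv").write_text(
        "\n".join(f"{t}\t{','.join(terms)}" for t, terms in sorted(target_terms.items()))
        + "\n"
    )
    (outdir / "model_targets.tsv").write_text("\n".join(grouping_lines) + "\n")
    with open(outdir / "gdt.tsv", "w") as fh:
        write_gdt_table(gdt, fh)


def inflate_z(slist: Slist, factor: float) -> Slist:
    """Scale every Z-score of one Slist — a planted neighborhood outlier."""
    return Slist(
        model_id=slist.model_id,
        records=tuple(
            SlistRecord(r.neighbor_id, r.z_score * factor, r.fs)
            for r in slist.records
        ),
        n_input_neighbors=slist.n_input_neighbors,
        n_unannotated=slist.n_unannotated,
    )
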