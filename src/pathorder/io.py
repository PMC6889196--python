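"""Reading mutation and pathway inputs; cohort filtering; category regrouping.

Handles MAF-style somatic mutation tables (TCGA column names), GMT gene-set
files and optional per-mutation score overrides, extraction of PolyPhen-2
functional-impact scores, removal of hyper-mutated samples, and the regrouping
of overlapping pathways into mutually exclusive categories (A' = A \\ B,
AB = A n B, B' = B \\ A) that the pairwise likelihood operates on.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .likelihood import PatientProfile

__all__ = [
    "MutationRecord",
    "PathwayDefinition",
    "CategorySet",
    "ScorePolicy",
    "read_maf",
    "write_maf",
    "read_gene_sets",
    "write_gene_sets",
    "read_score_overrides",
    "filter_hypermutated",
    "regroup_overlapping",
    "regroup_atomic",
    "build_pair_dataset",
]

# MAF Variant_Classification values retained (non-silent) and their class labels
_VARIANT_CLASS = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "Splice_Site": "splice",
    "In_Frame_Del": "in_frame_indel",
    "In_Frame_Ins": "in_frame_indel",
    "Nonstop_Mutation": "other_nonsilent",
    "Translation_Start_Site": "other_nonsilent",
}
#: classes that truncate or disrupt the protein; assigned score 1 when unannotated
TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift", "splice"})

_POLYPHEN_RE = re.compile(r"\(([\d.eE+-]+)\)")


@dataclass(frozen=True)
class MutationRecord:
    """One retained non-silent mutation call."""

    sample_id: str
    gene: str
    variant_class: str
    impact_score: float
    score_source: str = "annotated"  # annotated | imputed | override

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not (0.0 <= self.impact_score <= 1.0):
            raise ValueError("impact score must lie in [0, 1]")


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has an empty gene set")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass(frozen=True)
class CategorySet:
    """Mutually exclusive gene categories derived from (possibly overlapping)
    pathways.  ``alters[label]`` is the set of original pathway names a
    functional mutation in that category alters."""

    categories: tuple[str, ...]
    category_genes: Mapping[str, frozenset[str]]
    alters: Mapping[str, frozenset[str]]
    pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        genes = {}
        seen: set[str] = set()
        for label in self.categories:
            gs = frozenset(self.category_genes[label])
            if gs & seen:
                raise ValueError("category gene sets must be pairwise disjoint")
            seen |= gs
            genes[label] = gs
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "category_genes", genes)
        object.__setattr__(
            self, "alters", {k: frozenset(v) for k, v in self.alters.items()}
        )

    def category_of(self, gene: str) -> str | None:
        for label in self.categories:
            if gene in self.category_genes[label]:
                return label
        return None


@dataclass(frozen=True)
class ScorePolicy:
    """How functional-impact scores are obtained from a MAF.

    PolyPhen-2 annotates missense variants only; unannotated missense records
    get ``missing_missense`` (default 0.5, maximally uninformative) and
    truncating classes (nonsense/frameshift/splice) get ``truncating``
    (default 1.0, presumed loss of function).
    """

    score_column: str = "PolyPhen"
    missing_missense: float = 0.5
    truncating: float = 1.0
    overrides: Mapping[tuple[str, str], float] | None = None


def _parse_score_cell(cell: str) -> float | None:
    """Accept 'probably_damaging(0.98)' MAF dialect or a bare numeric cell."""
    cell = cell.strip()
    if not cell or cell in {".", "NA", "None", "none"}:
        return None
    m = _POLYPHEN_RE.search(cell)
    text = m.group(1) if m else cell
    try:
        value = float(text)
    except ValueError:
        return None
    if 0.0 <= value <= 1.0:
        return value
    return None


def read_maf(
    path, score_policy: ScorePolicy | None = None
) -> dict[str, list[MutationRecord]]:
    """Parse a tab-delimited MAF into records grouped by sample.

    Silent/intronic/UTR classes are dropped at parse time.  Each retained
    record carries an impact score per the policy; unparseable score cells
    trigger a warning and imputation.
    """
    policy = score_policy or ScorePolicy()
    with open(path) as fh:
        header = None
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append(fields)
    if header is None:
        raise ValueError(f"{path}: empty MAF")
    col = {name: i for i, name in enumerate(header)}
    for required in ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"):
        if required not in col:
            raise ValueError(f"{path}: missing mandatory MAF column {required!r}")
    score_idx = col.get(policy.score_column)

    cohort: dict[str, list[MutationRecord]] = {}
    for fields in rows:
        vclass = _VARIANT_CLASS.get(fields[col["Variant_Classification"]])
        if vclass is None:
            continue  # silent / synonymous / non-coding
        gene = fields[col["Hugo_Symbol"]]
        sample = fields[col["Tumor_Sample_Barcode"]]
        score = None
        source = "annotated"
        if policy.overrides and (sample, gene) in policy.overrides:
            score = policy.overrides[(sample, gene)]
            source = "override"
        elif score_idx is not None and score_idx < len(fields):
            cell = fields[score_idx]
            score = _parse_score_cell(cell)
            if score is None and cell.strip() not in {"", ".", "NA"}:
                warnings.warn(
                    f"{sample}/{gene}: unparseable score cell {cell!r}, imputing"
                )
        if score is None:
            source = "imputed"
            score = (
                policy.truncating
                if vclass in TRUNCATING_CLASSES
                else policy.missing_missense
            )
        cohort.setdefault(sample, []).append(
            MutationRecord(sample, gene, vclass, score, source)
        )
    return cohort


_CLASS_TO_MAF = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "frameshift": "Frame_Shift_Del",
    "splice": "Splice_Site",
    "in_frame_indel": "In_Frame_Del",
    "other_nonsilent": "Nonstop_Mutation",
}


def write_maf(cohort: Mapping[str, Sequence[MutationRecord]], path) -> None:
    """Write records back to a minimal MAF (scores in the PolyPhen column)."""
    with open(path, "w") as fh:
        fh.write("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tPolyPhen\n")
        for sample in sorted(cohort):
            for rec in cohort[sample]:
                fh.write(
                    f"{rec.gene}\t{sample}\t{_CLASS_TO_MAF[rec.variant_class]}\t"
                    f"{rec.impact_score:.10g}\n"
                )


def read_gene_sets(path) -> list[PathwayDefinition]:
    """Parse a GMT file (name, description, tab-separated genes)."""
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g.strip() for g in parts[2:]):
                raise ValueError(f"{path}:{lineno}: gene set with no genes")
            name = parts[0]
            genes = [g.strip() for g in parts[2:] if g.strip()]
            unique = set(genes)
            if len(unique) < len(genes):
                warnings.warn(f"{path}:{lineno}: duplicate genes in {name!r} deduplicated")
            pathways.append(PathwayDefinition(name, frozenset(unique)))
    return pathways


def write_gene_sets(pathways: Iterable[PathwayDefinition], path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, "na", *sorted(pw.genes)]) + "\n")


def read_score_overrides(path) -> dict[tuple[str, str], float]:
    """TSV with header sample_id, gene, protein_change, score -> override map."""
    overrides: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for required in ("sample_id", "gene", "score"):
            if required not in col:
                raise ValueError(f"{path}: missing override column {required!r}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                continue
            score = float(fields[col["score"]])
            overrides[(fields[col["sample_id"]], fields[col["gene"]])] = score
    return overrides


def filter_hypermutated(
    cohort: Mapping[str, Sequence[MutationRecord]], fraction: float
) -> dict[str, list[MutationRecord]]:
    """Remove the ceil(fraction * n) samples with the highest non-silent
    mutation counts (hyper-mutated tumors follow a different mutational
    process).  Ties broken by sample id for determinism."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    n = len(cohort)
    n_drop = math.ceil(fraction * n)
    ranked = sorted(cohort, key=lambda s: (-len(cohort[s]), s))
    dropped = set(ranked[:n_drop])
    return {s: list(cohort[s]) for s in cohort if s not in dropped}


def regroup_overlapping(pA: PathwayDefinition, pB: PathwayDefinition) -> CategorySet:
    """Split two pathways into mutually exclusive categories A', AB, B'.

    Mutations in A' or B' discriminate the order of A and B; mutations in the
    shared set AB alter both pathways simultaneously and carry the P(A=B)
    mass.  AB is omitted when the pathways are disjoint.
    """
    if pA.genes == pB.genes:
        raise ValueError(
            f"pathways {pA.name!r} and {pB.name!r} identical; order not identifiable"
        )
    a_only = pA.genes - pB.genes
    shared = pA.genes & pB.genes
    b_only = pB.genes - pA.genes
    label_a, label_ab, label_b = f"{pA.name}'", f"{pA.name}*{pB.name}", f"{pB.name}'"
    categories = [label_a]
    genes = {label_a: a_only}
    alters = {label_a: frozenset({pA.name})}
    if shared:
        categories.append(label_ab)
        genes[label_ab] = shared
        alters[label_ab] = frozenset({pA.name, pB.name})
    categories.append(label_b)
    genes[label_b] = b_only
    alters[label_b] = frozenset({pB.name})
    return CategorySet(tuple(categories), genes, alters, (pA.name, pB.name))


def regroup_atomic(pathways: Sequence[PathwayDefinition]) -> CategorySet:
    """Regroup any number of pathways into atomic intersection categories
    (one category per non-empty pathway-membership signature)."""
    membership: dict[frozenset[str], set[str]] = {}
    for gene in {g for pw in pathways for g in pw.genes}:
        sig = frozenset(pw.name for pw in pathways if gene in pw.genes)
        membership.setdefault(sig, set()).add(gene)
    labels = {}
    for sig in membership:
        labels[sig] = "*".join(sorted(sig))
    order = sorted(membership, key=lambda s: labels[s])
    categories = tuple(labels[s] for s in order)
    genes = {labels[s]: frozenset(membership[s]) for s in order}
    alters = {labels[s]: s for s in order}
    return CategorySet(categories, genes, alters, tuple(pw.name for pw in pathways))


def build_pair_dataset(
    cohort: Mapping[str, Sequence[MutationRecord]],
    cs: CategorySet,
    include_other: bool = False,
) -> list[PatientProfile]:
    """Map each mutation to its category and assemble patient profiles.

    Mutations in genes outside every category are discarded by default
    (``include_other`` adds an 'other' bucket); patients with no retained
    mutations contribute a constant likelihood factor and are dropped.
    """
    profiles = []
    for sample in sorted(cohort):
        scores: dict[str, list[float]] = {c: [] for c in cs.categories}
        if include_other:
            scores["other"] = []
        for rec in cohort[sample]:
            label = cs.category_of(rec.gene)
            if label is None:
                if include_other:
                    scores["other"].append(rec.impact_score)
                continue
            scores[label].append(rec.impact_score)
        counts = {c: len(v) for c, v in scores.items()}
        if sum(counts.values()) == 0:
            continue
        profiles.append(
            PatientProfile(sample, counts, {c: tuple(v) for c, v in scores.items()})
        )
    return profiles
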