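"""Pathway-completeness auditing from EC-number annotations.

An amino-acid biosynthesis pathway is encoded as one or more variants —
ordered chains of reaction steps, each satisfiable by any of a set of EC
numbers.  An organism, represented solely by its annotated EC complement,
is *complete* for an amino acid when at least one variant has every step
covered.  The audit also reports, per amino acid, the best (fewest
missing steps) variant and its missing steps: the minimal engineering
set needed to restore prototrophy, the quantity that identified the
three-step valine gap in CHO cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ECNumber",
    "ReactionStep",
    "PathwayVariant",
    "PathwayCatalog",
    "OrganismAnnotation",
    "CompletenessReport",
    "AMINO_ACIDS",
    "ESSENTIAL_AMINO_ACIDS",
    "CatalogFormatError",
    "CatalogValidationError",
    "load_packaged_catalog",
    "parse_catalog",
    "write_catalog",
    "parse_annotations",
    "variant_complete",
    "audit",
    "missing_steps_for_host",
    "count_catalog_genes",
]

#: The twenty canonical amino acids, three-letter codes.
AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: The nine essential amino acids whose biosynthesis metazoans lost.
ESSENTIAL_AMINO_ACIDS = frozenset(
    {"His", "Ile", "Leu", "Lys", "Met", "Phe", "Thr", "Trp", "Val"}
)

WILDCARD = "x"


class CatalogFormatError(ValueError):
    """A catalog or annotation file does not parse."""


class CatalogValidationError(ValueError):
    """A parsed catalog violates a structural invariant."""


@dataclass(frozen=True, order=True)
class ECNumber:
    """A four-field Enzyme Commission number.

    The serial (fourth) field may be the wildcard ``"x"``, which matches
    any serial within the same sub-subclass; databases differ in how far
    they resolve an activity, and a step defined at sub-subclass depth
    should not fail the audit on serial granularity alone.
    """

    value: str

    def __post_init__(self) -> None:
        parts = self.value.split(".")
        if len(parts) != 4:
            raise CatalogFormatError(
                f"EC number {self.value!r} must have four dot-separated fields"
            )
        for p in parts[:3]:
            if not p.isdigit() or int(p) < 1:
                raise CatalogFormatError(
                    f"EC number {self.value!r}: field {p!r} must be a positive integer"
                )
        serial = parts[3]
        if serial != WILDCARD and (not serial.isdigit() or int(serial) < 1):
            raise CatalogFormatError(
                f"EC number {self.value!r}: serial must be a positive integer "
                f"or the wildcard {WILDCARD!r}"
            )

    @property
    def prefix(self) -> str:
        return self.value.rsplit(".", 1)[0]

    @property
    def is_wildcard(self) -> bool:
        return self.value.endswith("." + WILDCARD)

    def matches(self, annotated: "ECNumber") -> bool:
        """Exact four-field match, or same sub-subclass under a wildcard."""
        if self.is_wildcard or annotated.is_wildcard:
            return self.prefix == annotated.prefix
        return self.value == annotated.value


@dataclass(frozen=True)
class ReactionStep:
    step_id: str
    ec_options: frozenset[ECNumber]
    substrate: str
    product: str

    def __post_init__(self) -> None:
        if not self.ec_options:
            raise CatalogValidationError(
                f"step {self.step_id!r} has no EC options"
            )

    def satisfied_by(self, ec_set: frozenset[ECNumber]) -> bool:
        return any(opt.matches(ec) for opt in self.ec_options for ec in ec_set)


@dataclass(frozen=True)
class PathwayVariant:
    variant_id: str
    amino_acid: str
    steps: tuple[ReactionStep, ...]
    gene_symbols: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.steps:
            raise CatalogValidationError(
                f"variant {self.variant_id!r} has no steps"
            )
        if self.amino_acid not in AMINO_ACIDS:
            raise CatalogValidationError(
                f"variant {self.variant_id!r}: unknown amino acid "
                f"{self.amino_acid!r}"
            )
        seen = set()
        for step in self.steps:
            if step.step_id in seen:
                raise CatalogValidationError(
                    f"variant {self.variant_id!r}: duplicate step "
                    f"{step.step_id!r}"
                )
            seen.add(step.step_id)
        for a, b in zip(self.steps, self.steps[1:]):
            if a.product != b.substrate:
                raise CatalogValidationError(
                    f"variant {self.variant_id!r}: step {a.step_id!r} yields "
                    f"{a.product!r} but step {b.step_id!r} consumes "
                    f"{b.substrate!r}"
                )


@dataclass(frozen=True)
class PathwayCatalog:
    variants: tuple[PathwayVariant, ...]

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise CatalogValidationError("duplicate variant_id in catalog")

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(
            aa for aa in AMINO_ACIDS if any(v.amino_acid == aa for v in self.variants)
        )

    def variants_for(self, amino_acid: str) -> tuple[PathwayVariant, ...]:
        return tuple(
            sorted(
                (v for v in self.variants if v.amino_acid == amino_acid),
                key=lambda v: v.variant_id,
            )
        )

    def all_ecs(self) -> frozenset[ECNumber]:
        return frozenset(
            ec for v in self.variants for s in v.steps for ec in s.ec_options
        )


@dataclass(frozen=True)
class OrganismAnnotation:
    """An organism reduced to its set of annotated EC numbers."""

    organism_id: str
    ec_set: frozenset[ECNumber] = frozenset()


@dataclass
class CompletenessReport:
    """Audit outcome for every (organism, amino acid) pair.

    ``rows`` has one entry per pair with keys organism_id, amino_acid,
    status (complete | incomplete | undefined), best_variant_id,
    missing_count and missing_steps (ordered step ids).
    """

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df["missing_steps"] = df["missing_steps"].map(";".join)
        return df

    def presence_matrix(self) -> pd.DataFrame:
        """Wide organisms x amino-acids matrix of 1 (complete) / 0."""
        df = pd.DataFrame(self.rows)
        df["present"] = (df["status"] == "complete").astype(int)
        return df.pivot(index="organism_id", columns="amino_acid", values="present")

    def lookup(self, organism_id: str, amino_acid: str) -> dict:
        for row in self.rows:
            if row["organism_id"] == organism_id and row["amino_acid"] == amino_acid:
                return row
        raise KeyError((organism_id, amino_acid))

    def incomplete_amino_acids(self, organism_id: str) -> list[str]:
        return [
            r["amino_acid"]
            for r in self.rows
            if r["organism_id"] == organism_id and r["status"] == "incomplete"
        ]


_COLUMNS = [
    "variant_id",
    "amino_acid",
    "step_index",
    "step_id",
    "ec_options",
    "substrate",
    "product",
    "gene_symbols",
]


def _catalog_from_records(records: list[dict]) -> PathwayCatalog:
    by_variant: dict[str, list[dict]] = {}
    for rec in records:
        by_variant.setdefault(str(rec["variant_id"]), []).append(rec)
    variants = []
    for variant_id, recs in by_variant.items():
        recs = sorted(recs, key=lambda r: int(r["step_index"]))
        steps = []
        genes: set[str] = set()
        for rec in recs:
            ecs = frozenset(
                ECNumber(tok) for tok in str(rec["ec_options"]).split(";") if tok
            )
            steps.append(
                ReactionStep(
                    step_id=str(rec["step_id"]),
                    ec_options=ecs,
                    substrate=str(rec["substrate"]),
                    product=str(rec["product"]),
                )
            )
            gene_field = rec.get("gene_symbols", "") or ""
            genes.update(tok for tok in str(gene_field).split(";") if tok)
        variants.append(
            PathwayVariant(
                variant_id=variant_id,
                amino_acid=str(recs[0]["amino_acid"]),
                steps=tuple(steps),
                gene_symbols=frozenset(genes),
            )
        )
    variants.sort(key=lambda v: v.variant_id)
    return PathwayCatalog(tuple(variants))


def parse_catalog(path: str | Path) -> PathwayCatalog:
    """Read a pathway catalog from TSV (or JSON with the same fields).

    Raises :class:`CatalogFormatError` for malformed EC strings (naming
    the offending line) and :class:`CatalogValidationError` for broken
    substrate/product chains.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise CatalogFormatError(f"{path}: JSON catalog must be a list")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise CatalogFormatError(
                f"{path}: missing columns {sorted(missing)}"
            )
        records = df.to_dict("records")
    out_records = []
    for i, rec in enumerate(records, start=2):
        try:
            for tok in str(rec["ec_options"]).split(";"):
                if tok:
                    ECNumber(tok)
        except CatalogFormatError as exc:
            raise CatalogFormatError(f"{path}, line {i}: {exc}") from None
        out_records.append(rec)
    return _catalog_from_records(out_records)


def write_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    """Write the normalized TSV form (sorted variants, sorted EC options);
    ``write(parse(x))`` is a fixed point."""
    rows = []
    for variant in sorted(catalog.variants, key=lambda v: v.variant_id):
        genes = ";".join(sorted(variant.gene_symbols))
        for idx, step in enumerate(variant.steps, start=1):
            rows.append(
                {
                    "variant_id": variant.variant_id,
                    "amino_acid": variant.amino_acid,
                    "step_index": idx,
                    "step_id": step.step_id,
                    "ec_options": ";".join(
                        sorted(ec.value for ec in step.ec_options)
                    ),
                    "substrate": step.substrate,
                    "product": step.product,
                    "gene_symbols": genes,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def load_packaged_catalog() -> PathwayCatalog:
    """The catalog shipped with the package: E. coli-mined biosynthetic
    routes for all twenty canonical amino acids."""
    ref = resources.files("prototroph.data") / "ecoli_amino_acid_pathways.tsv"
    with resources.as_file(ref) as path:
        return parse_catalog(path)


def parse_annotations(path: str | Path) -> list[OrganismAnnotation]:
    """Read long-format organism annotations (organism_id, ec_number)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("organism_id", "ec_number"):
        if col not in df.columns:
            raise CatalogFormatError(f"{path}: missing column {col!r}")
    out = []
    for organism_id, grp in df.groupby("organism_id", sort=True):
        out.append(
            OrganismAnnotation(
                organism_id=str(organism_id),
                ec_set=frozenset(ECNumber(v) for v in grp["ec_number"]),
            )
        )
    return out


def variant_complete(
    annotation: OrganismAnnotation, variant: PathwayVariant
) -> tuple[bool, list[str]]:
    """Check one variant: every step needs at least one of its EC options
    in the annotation.  Returns (complete, missing step ids in order)."""
    missing = [
        step.step_id
        for step in variant.steps
        if not step.satisfied_by(annotation.ec_set)
    ]
    return (not missing, missing)


def _best_variant(
    annotation: OrganismAnnotation, variants: tuple[PathwayVariant, ...]
) -> tuple[PathwayVariant, list[str]]:
    # variants arrive sorted by variant_id, so min() on missing-count alone
    # realizes the lexicographic tie-break
    best = None
    best_missing: list[str] = []
    for variant in variants:
        _, missing = variant_complete(annotation, variant)
        if best is None or len(missing) < len(best_missing):
            best, best_missing = variant, missing
    assert best is not None
    return best, best_missing


def audit(
    annotations: list[OrganismAnnotation] | OrganismAnnotation,
    catalog: PathwayCatalog,
) -> CompletenessReport:
    """Audit every organism against every amino acid of the catalog.

    An amino acid with no catalog variant is reported as ``undefined``
    rather than incomplete, so catalog gaps are not mistaken for
    auxotrophies.
    """
    if isinstance(annotations, OrganismAnnotation):
        annotations = [annotations]
    ids = [a.organism_id for a in annotations]
    if len(ids) != len(set(ids)):
        raise ValueError("organism ids must be unique")
    report = CompletenessReport()
    for annotation in sorted(annotations, key=lambda a: a.organism_id):
        for amino_acid in AMINO_ACIDS:
            variants = catalog.variants_for(amino_acid)
            if not variants:
                report.rows.append(
                    {
                        "organism_id": annotation.organism_id,
                        "amino_acid": amino_acid,
                        "status": "undefined",
                        "best_variant_id": None,
                        "missing_count": 0,
                        "missing_steps": [],
                    }
                )
                continue
            best, missing = _best_variant(annotation, variants)
            report.rows.append(
                {
                    "organism_id": annotation.organism_id,
                    "amino_acid": amino_acid,
                    "status": "complete" if not missing else "incomplete",
                    "best_variant_id": best.variant_id,
                    "missing_count": len(missing),
                    "missing_steps": missing,
                }
            )
    return report


def missing_steps_for_host(
    annotation: OrganismAnnotation, amino_acid: str, catalog: PathwayCatalog
) -> list[ReactionStep]:
    """The ordered missing steps of the best variant for one amino acid —
    the engineering target list for restoring its biosynthesis."""
    variants = catalog.variants_for(amino_acid)
    if not variants:
        raise KeyError(f"amino acid {amino_acid!r} has no variant in catalog")
    best, missing = _best_variant(annotation, variants)
    wanted = set(missing)
    return [step for step in best.steps if step.step_id in wanted]


def count_catalog_genes(catalog: PathwayCatalog, amino_acids) -> int:
    """Distinct enzyme-coding genes across all variants of the given
    amino acids (union of gene_symbols; shared genes counted once)."""
    amino_acids = set(amino_acids)
    unknown = amino_acids - set(catalog.amino_acids)
    if unknown:
        raise KeyError(f"amino acids not in catalog: {sorted(unknown)}")
    genes: set[str] = set()
    for variant in catalog.variants:
        if variant.amino_acid in amino_acids:
            genes |= variant.gene_symbols
    return len(genes)
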