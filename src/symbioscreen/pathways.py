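"""Reaction-by-reaction provisioning of metabolic pathways across a
host-symbiont consortium.

Each reaction of a pathway can be covered by genes from up to four sources:
the primary symbiont (e.g. Portiera), the secondary symbiont (e.g.
Hamiltonella), host genes of insect origin, and host genes of bacterial
origin (HTGs).  A symbiont gene provides its reaction when it is intact
(pseudogenes and absent genes never provide); a host gene provides when its
transcript is bacteriocyte-enriched or flagged abundant.  Every reaction is
then assigned a provider class, pathways receive a complete/incomplete
verdict, and cross-symbiosis presence/expression matrices can be built and
compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Origin",
    "Status",
    "ProviderClass",
    "GeneOption",
    "Reaction",
    "GeneStatus",
    "ReactionAssignment",
    "StatusTable",
    "ComplementarityMatrix",
    "classify_reaction",
    "pathway_completeness",
    "cofactor_audit",
    "build_complementarity_matrix",
    "htg_function_overlap",
]


class Origin(str, Enum):
    SYMBIONT_A = "symbiont_A"
    SYMBIONT_B = "symbiont_B"
    HOST_INSECT = "host_insect"
    HOST_HTG = "host_HTG"


class Status(str, Enum):
    INTACT = "intact"
    PSEUDOGENE = "pseudogene"
    ABSENT = "absent"


class ProviderClass(str, Enum):
    UNFILLED = "unfilled"
    SYMBIONT_ONLY = "symbiont_only"
    SHARED_SYMBIONT_PAIR = "shared_symbiont_pair"
    HOST_COMPLEMENT_INSECT = "host_complement_insect"
    HOST_COMPLEMENT_HTG = "host_complement_HTG"
    DUPLICATED = "duplicated"


_SYMBIONT_ORIGINS = {Origin.SYMBIONT_A, Origin.SYMBIONT_B}
_HOST_ORIGINS = {Origin.HOST_INSECT, Origin.HOST_HTG}


@dataclass(frozen=True)
class GeneOption:
    gene: str
    origin: Origin


@dataclass(frozen=True)
class Reaction:
    id: str
    pathway: str
    options: tuple[GeneOption, ...]
    position: int

    def __post_init__(self) -> None:
        if not self.options:
            raise ValueError(f"reaction {self.id} has no gene options")


@dataclass(frozen=True)
class GeneStatus:
    """Presence/expression state of one gene in one genome.

    ``expression_enriched``/``abundant`` apply to host genes (bacteriocyte
    transcript evidence); ``expression_reduced`` marks symbiont genes whose
    transcript abundance is significantly lower than pathway neighbours
    (e.g. genes likely en route to pseudogenisation, kept as intact).
    """

    gene: str
    origin: Origin
    status: Status = Status.INTACT
    expression_enriched: bool = False
    expression_reduced: bool = False
    abundant: bool = False

    def __post_init__(self) -> None:
        if self.status is not Status.INTACT and self.expression_enriched:
            raise ValueError(
                f"{self.gene}: a {self.status.value} gene cannot be expression-enriched"
            )

    @property
    def provides(self) -> bool:
        if self.status is not Status.INTACT:
            return False
        if self.origin in _HOST_ORIGINS:
            return self.expression_enriched or self.abundant
        return True


class StatusTable:
    """GeneStatus records indexed by (gene, origin)."""

    def __init__(self, statuses: Iterable[GeneStatus]):
        self._by_key: dict[tuple[str, Origin], GeneStatus] = {}
        for s in statuses:
            self._by_key[(s.gene, s.origin)] = s

    def get(self, option: GeneOption) -> GeneStatus:
        try:
            return self._by_key[(option.gene, option.origin)]
        except KeyError:
            raise KeyError(
                f"no status for gene {option.gene!r} (origin {option.origin.value})"
            ) from None

    def __iter__(self):
        return iter(self._by_key.values())


@dataclass(frozen=True)
class ReactionAssignment:
    reaction_id: str
    provider_class: ProviderClass
    providers: tuple[tuple[Origin, str], ...]


def classify_reaction(reaction: Reaction, statuses: StatusTable) -> ReactionAssignment:
    """Assign a provider class to one reaction.

    Precedence: unfilled (no provider) -> symbiont_only (a single symbiont)
    -> shared_symbiont_pair (both symbionts, no host) -> host complement
    (host provider, no intact symbiont gene; insect- vs bacterial-origin
    host gene) -> duplicated (host provider alongside an intact symbiont
    gene).
    """
    providers: list[tuple[Origin, str]] = []
    for opt in reaction.options:
        if statuses.get(opt).provides:
            providers.append((opt.origin, opt.gene))

    origins = {o for o, _ in providers}
    sym = origins & _SYMBIONT_ORIGINS
    host = origins & _HOST_ORIGINS
    if not providers:
        cls = ProviderClass.UNFILLED
    elif not host:
        cls = (
            ProviderClass.SYMBIONT_ONLY
            if len(sym) == 1
            else ProviderClass.SHARED_SYMBIONT_PAIR
        )
    elif sym:
        cls = ProviderClass.DUPLICATED
    elif Origin.HOST_INSECT in host:
        cls = ProviderClass.HOST_COMPLEMENT_INSECT
    else:
        cls = ProviderClass.HOST_COMPLEMENT_HTG
    return ReactionAssignment(reaction.id, cls, tuple(providers))


@dataclass(frozen=True)
class PathwayVerdict:
    pathway: str
    complete: bool
    assignments: tuple[ReactionAssignment, ...]
    gaps: tuple[str, ...]


def pathway_completeness(
    pathway: Sequence[Reaction], statuses: StatusTable
) -> PathwayVerdict:
    """A pathway is complete iff every reaction has at least one provider."""
    if not pathway:
        raise ValueError("pathway must contain at least one reaction")
    ordered = sorted(pathway, key=lambda r: r.position)
    assignments = tuple(classify_reaction(r, statuses) for r in ordered)
    gaps = tuple(a.reaction_id for a in assignments if a.provider_class is ProviderClass.UNFILLED)
    return PathwayVerdict(
        pathway=ordered[0].pathway,
        complete=not gaps,
        assignments=assignments,
        gaps=gaps,
    )


def cofactor_audit(
    required_cofactors: Iterable[str],
    pathway_fixtures: Mapping[str, Sequence[Reaction]],
    statuses: StatusTable,
    organism_names: Mapping[Origin, str] | None = None,
) -> dict[str, str]:
    """Decide, per cofactor, which consortium member(s) can supply it.

    A cofactor is supplied by the organism whose biosynthetic pathway is
    complete; when completeness requires host genes filling reactions a
    symbiont lacks, the provider is ``joint(<symbiont>, host)``; a cofactor
    with an incomplete pathway is a ``gap``.
    """
    organism_names = organism_names or {
        Origin.SYMBIONT_A: "Portiera",
        Origin.SYMBIONT_B: "Hamiltonella",
    }
    out: dict[str, str] = {}
    for cofactor in required_cofactors:
        if cofactor not in pathway_fixtures:
            raise ValueError(f"no pathway fixture for cofactor {cofactor!r}")
        verdict = pathway_completeness(pathway_fixtures[cofactor], statuses)
        if not verdict.complete:
            out[cofactor] = "gap"
            continue
        sym_orgs: set[str] = set()
        host_essential = False
        for a in verdict.assignments:
            origins = {o for o, _ in a.providers}
            sym_here = origins & _SYMBIONT_ORIGINS
            sym_orgs |= {organism_names[o] for o in sym_here}
            if not sym_here:
                host_essential = True  # reaction filled by host alone
        if not sym_orgs:
            out[cofactor] = "host"
        elif host_essential:
            out[cofactor] = f"joint({', '.join(sorted(sym_orgs))}, host)"
        else:
            out[cofactor] = ", ".join(sorted(sym_orgs))
    return out


_CELL_VOCAB = {"+", "0", "?", ""}


@dataclass
class ComplementarityMatrix:
    """Symbiosis x gene-function matrix with the +/0/?/blank vocabulary.

    ``+`` present (symbiont columns) or abundant/enriched in bacteriocytes
    (host columns), ``0`` absent, ``?`` uncertain, blank no information.
    """

    table: pd.DataFrame  # index: symbiosis, columns: gene functions, str cells

    def __post_init__(self) -> None:
        bad = set(self.table.to_numpy().ravel()) - _CELL_VOCAB
        if bad:
            raise ValueError(f"cells outside vocabulary {{+,0,?,blank}}: {sorted(bad)}")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="symbiosis")

    @classmethod
    def from_tsv(cls, path) -> "ComplementarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="symbiosis", dtype=str, keep_default_na=False)
        return cls(df)


def build_complementarity_matrix(
    symbioses: Sequence[tuple[str, Mapping[str, str]]],
) -> ComplementarityMatrix:
    """Assemble the cross-symbiosis matrix from per-symbiosis cell mappings.

    All symbioses must share one column schema; unknown cells stay ``?`` and
    no-information cells stay blank.
    """
    if not symbioses:
        return ComplementarityMatrix(pd.DataFrame(dtype=str))
    schema = list(symbioses[0][1].keys())
    rows = {}
    for name, cells in symbioses:
        if list(cells.keys()) != schema:
            raise ValueError(f"column schema mismatch for symbiosis {name!r}")
        rows[name] = [str(cells[c]) for c in schema]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=schema)
    return ComplementarityMatrix(df)


def htg_function_overlap(
    function_sets: Mapping[str, Iterable[str]],
) -> dict[str, object]:
    """Cross-symbiosis comparison of HTG functional repertoires.

    Given, per symbiosis, the set of gene functions carried as HTGs, report
    which symbioses carry each function, the fraction of (function,
    symbiosis) gene records whose function occurs in exactly one symbiosis,
    per-symbiosis shared fractions, and functions present everywhere.
    """
    sets = {k: frozenset(v) for k, v in function_sets.items()}
    function_map: dict[str, tuple[str, ...]] = {}
    for name, funcs in sets.items():
        for f in funcs:
            function_map.setdefault(f, ())
    for f in function_map:
        function_map[f] = tuple(sorted(n for n, s in sets.items() if f in s))

    records = [(f, n) for n, s in sets.items() for f in s]
    unique = [(f, n) for f, n in records if len(function_map[f]) == 1]
    shared_frac = {
        name: (
            sum(1 for f in funcs if len(function_map[f]) > 1) / len(funcs)
            if funcs
            else 0.0
        )
        for name, funcs in sets.items()
    }
    universal = sorted(
        f for f, carriers in function_map.items() if len(carriers) == len(sets) > 0
    )
    return {
        "function_map": function_map,
        "n_records": len(records),
        "n_unique_records": len(unique),
        "fraction_unique": (len(unique) / len(records)) if records else 0.0,
        "per_symbiosis_shared_fraction": shared_frac,
        "universal_functions": universal,
    }
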