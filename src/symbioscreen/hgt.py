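"""HGT-index screening of transcripts for genes of bacterial origin.

A transcript assembled from an insect library can be a horizontally
transferred gene (HTG) of bacterial origin, an ordinary insect gene, a
symbiont transcript, or an environmental contaminant.  The screen compares
the best prokaryote and best eukaryote protein hits of each transcript:

    h = bitscore(best prokaryote hit) - bitscore(best eukaryote hit)

and retains candidates through a cascade of gates: h >= 30, best prokaryote
bitscore >= 100, ln(E_prok / E_euk) < -9, expression FPKM > 1, no hit to the
resident symbionts (Portiera, Hamiltonella), no blacklisted environmental
lineage, and a bacterial top hit with percent identity > 40.  A functional
whitelist (by default the biotin genes bioA and bioB, known HTGs in related
symbioses) rescues candidates that fail only the score gates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ScreenConfig",
    "AgeClass",
    "PresenceProfile",
    "best_hits",
    "hgt_index",
    "ln_evalue_ratio",
    "screen_htg",
    "check_symbiont_identity",
    "cross_species_presence",
]

#: lineages named as likely environmental contaminants in manual curation
DEFAULT_CONTAMINANT_BLACKLIST = (
    "Lachnospiraceae",
    "Wallemia sebi",
    "Sorangium cellulosum",
)

#: bacteriocyte-resident symbiont lineages whose transcripts must be excluded
DEFAULT_SYMBIONT_PATTERNS = ("Portiera", "Hamiltonella")

PROKARYOTE_DOMAINS = frozenset({"Bacteria", "Archaea"})


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and lineage lists for the screening cascade.

    Defaults are the published thresholds of the whitefly bacteriocyte
    screen; ``max_evalue_for_hit`` mirrors the E < 1e-10 reporting cutoff of
    the underlying searches (hits above it count as no hit).
    """

    min_h: float = 30.0
    min_prok_bitscore: float = 100.0
    max_ln_e_ratio: float = -9.0
    min_fpkm: float = 1.0
    min_tophit_identity: float = 40.0
    max_evalue_for_hit: float = 1e-10
    evalue_floor: float = 1e-180
    symbiont_patterns: tuple[str, ...] = DEFAULT_SYMBIONT_PATTERNS
    contaminant_blacklist: tuple[str, ...] = DEFAULT_CONTAMINANT_BLACKLIST
    whitelist: tuple[str, ...] = ("bioA", "bioB")

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "ScreenConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown screen config keys: {sorted(unknown)}")
        coerced: dict[str, object] = {}
        for key, value in data.items():
            if key in ("symbiont_patterns", "contaminant_blacklist", "whitelist"):
                coerced[key] = tuple(value)  # type: ignore[arg-type]
            else:
                coerced[key] = float(value)  # type: ignore[arg-type]
        return cls(**coerced)  # type: ignore[arg-type]


class AgeClass(str, Enum):
    ANCIENT = "ancient"
    B_TABACI_COMPLEX = "b_tabaci_complex"
    RECENT = "recent"


@dataclass(frozen=True)
class PresenceProfile:
    gene: str
    presence: Mapping[str, bool]
    age_class: AgeClass = field(compare=False)


_HIT_COLUMNS = {"qseqid", "sseqid", "pident", "evalue", "bitscore", "subject_domain"}


def _best_in(group: pd.DataFrame) -> pd.Series | None:
    if group.empty:
        return None
    g = group.sort_values(
        ["bitscore", "evalue", "sseqid"], ascending=[False, True, True], kind="mergesort"
    )
    return g.iloc[0]


def best_hits(
    hits: pd.DataFrame,
    query_id: str,
    max_evalue: float | None = None,
) -> tuple[pd.Series | None, pd.Series | None]:
    """Best prokaryote (Bacteria+Archaea) and best eukaryote hit of a query.

    Best = highest bitscore; ties broken by lower E-value, then lexicographic
    subject id.  Returns ``None`` for a partition with no (qualifying) hit.
    """
    missing = _HIT_COLUMNS - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    sub = hits[hits["qseqid"] == query_id]
    if max_evalue is not None:
        sub = sub[sub["evalue"] <= max_evalue]
    prok = _best_in(sub[sub["subject_domain"].isin(PROKARYOTE_DOMAINS)])
    euk = _best_in(sub[sub["subject_domain"] == "Eukaryota"])
    return prok, euk


def hgt_index(best_prok_bitscore: float, best_euk_bitscore: float | None) -> float:
    """h = B_prok - B_euk; a missing eukaryote hit contributes B_euk = 0."""
    if best_euk_bitscore is None:
        best_euk_bitscore = 0.0
    return float(best_prok_bitscore) - float(best_euk_bitscore)


def ln_evalue_ratio(
    e_prok: float, e_euk: float | None, floor: float = 1e-180
) -> float:
    """ln of the prokaryote:eukaryote E-value ratio, floored at ``floor``.

    A missing eukaryote hit is treated as E = 1.0 (no-hit convention); E = 0
    as reported by search tools is clamped to the floor before the log.
    """
    if e_prok < 0 or (e_euk is not None and e_euk < 0):
        raise ValueError("E-values must be non-negative")
    if e_euk is None:
        e_euk = 1.0
    return math.log(max(e_prok, floor)) - math.log(max(e_euk, floor))


def check_symbiont_identity(identity_pct: float) -> bool:
    """True when a candidate is sufficiently diverged from the symbiont
    homolog (amino-acid identity strictly below 50%) to rule out symbiont
    sequence contamination."""
    if not 0.0 <= identity_pct <= 100.0:
        raise ValueError("identity must be a percentage in [0, 100]")
    return identity_pct < 50.0


def _matches_any(lineage: str, patterns: Sequence[str]) -> bool:
    return any(p in lineage for p in patterns)


def screen_htg(
    hits: pd.DataFrame,
    fpkm: Mapping[str, float],
    config: ScreenConfig | None = None,
    annotations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Run the full screening cascade and emit one verdict row per query.

    ``fpkm`` maps query id to bacteriocyte FPKM (absent queries count as 0
    and fail the expression gate).  ``annotations`` maps query id to a gene
    symbol; symbols in ``config.whitelist`` can be retained even when the
    three score gates (h, bitscore, E-ratio) fail as a unit.  Queries without
    any prokaryote hit are not candidates and are omitted.

    Output columns: query_id, best_prok_bitscore, best_euk_bitscore, h,
    ln_e_ratio, fpkm, the per-gate boolean flags, and retained.
    """
    config = config or ScreenConfig()
    annotations = annotations or {}
    missing = (_HIT_COLUMNS | {"subject_lineage"}) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")

    rows = []
    for query in sorted(hits["qseqid"].astype(str).unique()):
        prok, euk = best_hits(hits, query, max_evalue=config.max_evalue_for_hit)
        if prok is None:
            continue  # no prokaryote hit: not an HTG candidate
        b_prok = float(prok["bitscore"])
        b_euk = None if euk is None else float(euk["bitscore"])
        h = hgt_index(b_prok, b_euk)
        lnr = ln_evalue_ratio(
            float(prok["evalue"]),
            None if euk is None else float(euk["evalue"]),
            floor=config.evalue_floor,
        )
        query_fpkm = float(fpkm.get(query, 0.0))

        top = _best_in(pd.concat([prok.to_frame().T, euk.to_frame().T]) if euk is not None
                       else prok.to_frame().T)
        top_is_bacterial = str(top["subject_domain"]) in PROKARYOTE_DOMAINS
        lineage = str(prok["subject_lineage"])

        flags = {
            "h_pass": h >= config.min_h,
            "bitscore_pass": b_prok >= config.min_prok_bitscore,
            "eratio_pass": lnr < config.max_ln_e_ratio,
            "fpkm_pass": query_fpkm > config.min_fpkm,
            "not_symbiont": not _matches_any(lineage, config.symbiont_patterns),
            "not_contaminant": not _matches_any(lineage, config.contaminant_blacklist),
            "tophit_bacterial_identity_pass": (
                top_is_bacterial and float(top["pident"]) > config.min_tophit_identity
            ),
            "whitelisted": annotations.get(query) in config.whitelist,
        }
        score_gates = flags["h_pass"] and flags["bitscore_pass"] and flags["eratio_pass"]
        retained = (
            flags["fpkm_pass"]
            and flags["not_symbiont"]
            and flags["not_contaminant"]
            and flags["tophit_bacterial_identity_pass"]
            and (score_gates or flags["whitelisted"])
        )
        rows.append(
            {
                "query_id": query,
                "best_prok_bitscore": b_prok,
                "best_euk_bitscore": 0.0 if b_euk is None else b_euk,
                "h": h,
                "ln_e_ratio": lnr,
                "fpkm": query_fpkm,
                **flags,
                "retained": retained,
            }
        )
    columns = [
        "query_id", "best_prok_bitscore", "best_euk_bitscore", "h", "ln_e_ratio",
        "fpkm", "h_pass", "bitscore_pass", "eratio_pass", "fpkm_pass",
        "not_symbiont", "not_contaminant", "tophit_bacterial_identity_pass",
        "whitelisted", "retained",
    ]
    return pd.DataFrame(rows, columns=columns)


def rederive_retained(verdicts: pd.DataFrame) -> pd.Series:
    """Recompute ``retained`` from the flags alone (consistency check)."""
    score = verdicts["h_pass"] & verdicts["bitscore_pass"] & verdicts["eratio_pass"]
    return (
        verdicts["fpkm_pass"]
        & verdicts["not_symbiont"]
        & verdicts["not_contaminant"]
        & verdicts["tophit_bacterial_identity_pass"]
        & (score | verdicts["whitelisted"])
    )


def cross_species_presence(
    candidate: str,
    presence_calls: Mapping[str, bool],
    outgroup_label: str,
) -> PresenceProfile:
    """Date a transfer by its presence across related species' transcriptomes.

    ``presence_calls`` maps dataset label (e.g. MED, AsiaII3, Tvap) to
    detected/not; presence in the outgroup dataset implies the transfer
    predates the split (ancient); presence in at least two non-outgroup
    datasets implies it is shared across the focal species complex; anything
    else is classed recent.
    """
    if not presence_calls:
        raise ValueError("presence_calls must cover at least one dataset")
    if outgroup_label not in presence_calls:
        raise ValueError(f"outgroup dataset {outgroup_label!r} not among presence calls")
    if presence_calls[outgroup_label]:
        age = AgeClass.ANCIENT
    else:
        n_in_complex = sum(
            bool(v) for k, v in presence_calls.items() if k != outgroup_label
        )
        age = AgeClass.B_TABACI_COMPLEX if n_in_complex >= 2 else AgeClass.RECENT
    return PresenceProfile(gene=candidate, presence=dict(presence_calls), age_class=age)
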