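"""Synthetic inputs and packaged fixtures for the whole pipeline.

Three kinds of inputs are produced so every downstream stage is testable
without any sequence download:

* two-library negative-binomial count tables with known enriched/depleted
  truth (stand-in for the bacteriocyte and whole-body RNA-seq libraries),
* homology-hit tables with planted bacterial-origin genes (HTGs) and three
  decoy classes (ordinary insect genes, symbiont transcripts, environmental
  contaminants),
* fixtures transcribed from the published whitefly tables and pathway maps
  (loaded from the YAML files shipped under ``symbioscreen/data``).

Simulated E-values are derived from bitscores as E = L_db * 2^-B with a
fixed nominal database size, so the bitscore and E-ratio screening gates are
mutually consistent on simulated data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .pathways import GeneOption, GeneStatus, Origin, Reaction, Status, StatusTable

__all__ = [
    "SimCountParams",
    "SimHgtParams",
    "SimulatedHits",
    "simulate_count_table",
    "simulate_hit_table",
    "Table1Fixture",
    "make_table1_fixture",
    "PathwayFixtures",
    "make_pathway_fixtures",
    "evalue_from_bitscore",
    "NOMINAL_DB_SIZE",
]

#: nominal search-space size linking simulated bitscores to E-values
NOMINAL_DB_SIZE = 1e9

HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "qstart", "qend",
    "sstart", "send", "evalue", "bitscore", "subject_domain", "subject_lineage",
]

_INSECT_LINEAGE = "Eukaryota;Metazoa;Arthropoda;Insecta;Hemiptera"
_SYMBIONT_LINEAGES = (
    "Bacteria;Proteobacteria;Gammaproteobacteria;Oceanospirillales;Candidatus Portiera aleyrodidarum",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Candidatus Hamiltonella defensa",
)
_CONTAMINANT_LINEAGES = (
    "Bacteria;Firmicutes;Clostridia;Lachnospirales;Lachnospiraceae",
    "Eukaryota;Fungi;Basidiomycota;Wallemiales;Wallemia sebi",
    "Bacteria;Proteobacteria;Deltaproteobacteria;Myxococcales;Sorangium cellulosum",
)
_PLANTED_LINEAGE = "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Pantoea"


def evalue_from_bitscore(bitscore: float, db_size: float = NOMINAL_DB_SIZE) -> float:
    """E = L_db * 2^-B; underflows cleanly to 0.0 for very large bitscores."""
    return db_size * math.pow(2.0, -bitscore)


@dataclass(frozen=True)
class SimCountParams:
    """Conditions for the two-library count simulation.

    Defaults emulate the published two-library design at desk scale:
    library depths are the published 52.4M/51.8M read totals scaled 1:100,
    mean_count chosen so expected totals match the depths, negative-binomial
    size 10 (``dispersion=None`` switches to Poisson sampling, the null
    model of the downstream tag-count test).
    """

    n_transcripts: int = 2000
    frac_enriched: float = 0.1
    frac_depleted: float = 0.1
    log2_effect: float = 2.0
    mean_count: float = 260.0
    dispersion: float | None = 10.0
    library_size_1: int = 524_000
    library_size_2: int = 518_000
    length_range: tuple[int, int] = (300, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if not (0 <= self.frac_enriched <= 1 and 0 <= self.frac_depleted <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_enriched + self.frac_depleted > 1:
            raise ValueError("frac_enriched + frac_depleted must not exceed 1")
        if self.log2_effect <= 0:
            raise ValueError("log2_effect must be positive")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be positive")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")
        if self.library_size_1 <= 0 or self.library_size_2 <= 0:
            raise ValueError("library sizes must be positive")
        if self.length_range[0] <= 0 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must be a positive, ordered interval")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float | None) -> np.ndarray:
    if size_param is None or math.isinf(size_param):
        return rng.poisson(mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_count_table(params: SimCountParams) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a two-library count table with exact truth-label fractions.

    Truth labels are assigned by deterministic index blocks before any
    sampling (first ``round(frac_enriched*n)`` transcripts enriched, next
    block depleted, remainder null), so class fractions are exact.  Library
    1 is the focal (bacteriocyte-style) library: enriched transcripts have
    their library-1 mean multiplied by ``2^log2_effect``, depleted ones
    divided by it.  Per-library means scale with library depth; expected
    totals match the library sizes up to the (unnormalised) mass the DE
    fold changes add, so null transcripts stay exactly calibrated to the
    nominal depth ratio.
    """
    n = params.n_transcripts
    rng = np.random.default_rng(params.seed)
    ids = np.array([f"t{i:06d}" for i in range(n)])
    n_enr = int(round(params.frac_enriched * n))
    n_dep = int(round(params.frac_depleted * n))
    truth = np.array(["null"] * n, dtype=object)
    truth[:n_enr] = "enriched"
    truth[n_enr : n_enr + n_dep] = "depleted"

    lengths = rng.integers(params.length_range[0], params.length_range[1] + 1, size=n)
    fold = np.ones(n)
    fold[:n_enr] = 2.0**params.log2_effect
    fold[n_enr : n_enr + n_dep] = 2.0**-params.log2_effect

    n_bar = 0.5 * (params.library_size_1 + params.library_size_2)
    mu1 = params.mean_count * (params.library_size_1 / n_bar) * fold
    mu2 = params.mean_count * (params.library_size_2 / n_bar) * np.ones(n)
    counts1 = _nb_draw(rng, mu1, params.dispersion)
    counts2 = _nb_draw(rng, mu2, params.dispersion)

    table = pd.DataFrame(
        {
            "transcript_id": ids,
            "length_bp": lengths.astype(int),
            "count_lib1": counts1.astype(int),
            "count_lib2": counts2.astype(int),
        }
    )
    return table, pd.Series(truth, index=ids, name="truth")


@dataclass(frozen=True)
class SimHgtParams:
    """Conditions for the planted-HTG hit-table simulation.

    Planted HTGs clear every screening gate by at least ``bitscore_margin``
    bits; insect decoys have a eukaryote best hit above their prokaryote
    best hit; symbiont and contaminant decoys pass the score gates but carry
    excluded lineages.
    """

    n_planted_htg: int = 10
    n_insect_decoys: int = 30
    n_contaminant_decoys: int = 10
    n_symbiont_decoys: int = 10
    bitscore_margin: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_planted_htg", "n_insect_decoys", "n_contaminant_decoys",
                     "n_symbiont_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bitscore_margin < 0:
            raise ValueError("bitscore_margin must be non-negative")


class SimulatedHits(NamedTuple):
    hits: pd.DataFrame
    truth: pd.Series
    fpkm: dict[str, float]


def _hit_row(rng, query: str, subject: str, domain: str, lineage: str,
             bitscore: float, pident: float) -> dict:
    aln = int(rng.integers(100, 400))
    qstart = int(rng.integers(1, 50))
    sstart = int(rng.integers(1, 50))
    bitscore = round(bitscore, 1)  # written precision; E-value derived from it
    return {
        "qseqid": query,
        "sseqid": subject,
        "pident": round(pident, 2),
        "length": aln,
        "qstart": qstart,
        "qend": qstart + aln * 3 - 1,
        "sstart": sstart,
        "send": sstart + aln - 1,
        "evalue": evalue_from_bitscore(bitscore),
        "bitscore": round(bitscore, 1),
        "subject_domain": domain,
        "subject_lineage": lineage,
    }


def simulate_hit_table(params: SimHgtParams) -> SimulatedHits:
    """Simulate an extended-BLAST hit table with known per-query truth.

    Returns the hit table, a truth series (planted_htg / null / symbiont /
    contaminant), and an FPKM mapping (every query expressed above the
    FPKM > 1 gate, so lineage and score gates alone decide retention).
    """
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []
    truth: dict[str, str] = {}
    fpkm: dict[str, float] = {}
    m = params.bitscore_margin

    def _passing_scores() -> tuple[float, float]:
        b_euk = rng.uniform(70.0, 90.0)
        b_prok = max(100.0 + m, b_euk + 30.0 + m) + rng.uniform(0.0, 20.0)
        return b_prok, b_euk

    for i in range(params.n_planted_htg):
        q = f"htg_{i:03d}"
        b_prok, b_euk = _passing_scores()
        rows.append(_hit_row(rng, q, f"WP_{i:06d}", "Bacteria", _PLANTED_LINEAGE,
                             b_prok, rng.uniform(45.0, 80.0)))
        rows.append(_hit_row(rng, q, f"XP_{i:06d}", "Eukaryota", _INSECT_LINEAGE,
                             b_euk, rng.uniform(30.0, 60.0)))
        truth[q] = "planted_htg"
        fpkm[q] = float(rng.uniform(5.0, 500.0))

    for i in range(params.n_insect_decoys):
        q = f"insect_{i:03d}"
        b_euk = rng.uniform(150.0, 250.0)
        b_prok = b_euk - rng.uniform(40.0, 80.0)
        rows.append(_hit_row(rng, q, f"XP_{1000+i:06d}", "Eukaryota", _INSECT_LINEAGE,
                             b_euk, rng.uniform(60.0, 95.0)))
        rows.append(_hit_row(rng, q, f"WP_{1000+i:06d}", "Bacteria", _PLANTED_LINEAGE,
                             b_prok, rng.uniform(45.0, 70.0)))
        truth[q] = "null"
        fpkm[q] = float(rng.uniform(5.0, 500.0))

    for i in range(params.n_symbiont_decoys):
        q = f"symb_{i:03d}"
        b_prok, b_euk = _passing_scores()
        lineage = _SYMBIONT_LINEAGES[i % len(_SYMBIONT_LINEAGES)]
        rows.append(_hit_row(rng, q, f"SYM_{i:06d}", "Bacteria", lineage,
                             b_prok, rng.uniform(45.0, 80.0)))
        rows.append(_hit_row(rng, q, f"XP_{2000+i:06d}", "Eukaryota", _INSECT_LINEAGE,
                             b_euk, rng.uniform(30.0, 60.0)))
        truth[q] = "symbiont"
        fpkm[q] = float(rng.uniform(5.0, 500.0))

    for i in range(params.n_contaminant_decoys):
        q = f"contam_{i:03d}"
        b_prok, b_euk = _passing_scores()
        lineage = _CONTAMINANT_LINEAGES[i % len(_CONTAMINANT_LINEAGES)]
        domain = "Eukaryota" if "Fungi" in lineage else "Bacteria"
        # fungal contaminants still need a prokaryote best hit to enter the
        # cascade; give them a blacklisted bacterial lineage instead
        if domain == "Eukaryota":
            lineage = _CONTAMINANT_LINEAGES[0]
        rows.append(_hit_row(rng, q, f"ENV_{i:06d}", "Bacteria", lineage,
                             b_prok, rng.uniform(45.0, 80.0)))
        rows.append(_hit_row(rng, q, f"XP_{3000+i:06d}", "Eukaryota", _INSECT_LINEAGE,
                             b_euk, rng.uniform(30.0, 60.0)))
        truth[q] = "contaminant"
        fpkm[q] = float(rng.uniform(5.0, 500.0))

    hits = pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)
    return SimulatedHits(hits, pd.Series(truth, name="truth"), fpkm)


class Table1Fixture(NamedTuple):
    expression: pd.DataFrame  # gene, description, FPKM pair, fold changes, intron, origin
    hits: pd.DataFrame        # extended BLAST dialect rows (synthetic scores)
    annotations: pd.DataFrame # gene symbol, presence calls per related dataset


def _data_text(name: str) -> str:
    return resources.files("symbioscreen.data").joinpath(name).read_text(encoding="utf-8")


def make_table1_fixture() -> Table1Fixture:
    """The ten published whitefly HTGs as a ready-to-screen fixture.

    FPKM values, fold changes, intron flags and donor lineages are the
    published ones; the per-gene hit bitscores are synthetic, constructed so
    the screening cascade retains all ten genes with bioA and bioB passing
    only through the functional whitelist (their h < 30).
    """
    data = yaml.safe_load(_data_text("table1.yaml"))
    expr_rows, hit_rows, annot_rows = [], [], []
    rng = np.random.default_rng(0)  # only for alignment-coordinate filler
    for g in data["genes"]:
        expr_rows.append(
            {
                "gene": g["gene"],
                "description": g["description"],
                "ec": g["ec"],
                "fpkm_bacteriocyte": g["fpkm_bacteriocyte"],
                "fpkm_wholebody": g["fpkm_wholebody"],
                "log2_ratio_rnaseq": g["log2_ratio_rnaseq"],
                "log2_ratio_qpcr": g["log2_ratio_qpcr"],
                "intron": g["intron"],
                "origin": g["origin"],
            }
        )
        hit = g["hit"]
        hit_rows.append(_hit_row(rng, g["gene"], f"prok|{g['gene']}", "Bacteria",
                                 hit["lineage"], hit["bitscore_prok"], hit["pident"]))
        hit_rows.append(_hit_row(rng, g["gene"], f"euk|{g['gene']}", "Eukaryota",
                                 _INSECT_LINEAGE, hit["bitscore_euk"],
                                 max(30.0, hit["pident"] - 15.0)))
        annot_rows.append({"gene": g["gene"], "annotation": g["gene"], **{
            f"present_{k}": v for k, v in g["presence"].items()}})
    return Table1Fixture(
        expression=pd.DataFrame(expr_rows),
        hits=pd.DataFrame(hit_rows, columns=HIT_TABLE_COLUMNS),
        annotations=pd.DataFrame(annot_rows),
    )


class PathwayFixtures(NamedTuple):
    pathways: dict[str, tuple[Reaction, ...]]
    statuses: StatusTable
    cofactor_classes: tuple[str, ...]
    table2_rows: tuple[tuple[str, dict[str, str]], ...]
    table2_metadata: dict
    htg_function_sets: dict[str, tuple[str, ...]]
    metadata: dict


def make_pathway_fixtures() -> PathwayFixtures:
    """Load the packaged pathway, matrix and HTG-overlap fixtures."""
    pw = yaml.safe_load(_data_text("pathways.yaml"))
    t2 = yaml.safe_load(_data_text("table2.yaml"))
    overlap = yaml.safe_load(_data_text("htg_functions_synthetic.yaml"))

    pathways: dict[str, tuple[Reaction, ...]] = {}
    for name, reactions in pw["pathways"].items():
        pathways[name] = tuple(
            Reaction(
                id=r["id"],
                pathway=name,
                options=tuple(
                    GeneOption(o["gene"], Origin(o["origin"])) for o in r["options"]
                ),
                position=pos,
            )
            for pos, r in enumerate(reactions, start=1)
        )
    statuses = StatusTable(
        GeneStatus(
            gene=s["gene"],
            origin=Origin(s["origin"]),
            status=Status(s.get("status", "intact")),
            expression_enriched=bool(s.get("expression_enriched", False)),
            expression_reduced=bool(s.get("expression_reduced", False)),
            abundant=bool(s.get("abundant", False)),
        )
        for s in pw["statuses"]
    )
    columns = t2["columns"]
    rows = tuple(
        (name, {c: str(row["cells"][c]) for c in columns})
        for name, row in t2["rows"].items()
    )
    return PathwayFixtures(
        pathways=pathways,
        statuses=statuses,
        cofactor_classes=tuple(pw["metadata"]["cofactor_classes"]),
        table2_rows=rows,
        table2_metadata=t2.get("metadata", {}),
        htg_function_sets={k: tuple(v) for k, v in overlap["function_sets"].items()},
        metadata=pw["metadata"],
    )
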