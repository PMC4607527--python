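"""Readers, writers, run configuration and end-to-end orchestration.

Tables travel as TSV.  Hit tables use the classic 12-column BLAST tabular
layout extended with ``subject_domain`` and ``subject_lineage`` columns and
no header row; count and result tables carry a header.  Every file written
here starts with a ``#`` provenance line recording the tool version, a hash
of the run configuration, and the seed.  Coordinates are 1-based inclusive
on disk (BLAST convention).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import LibraryPair, call_differential, round_half_up
from .hgt import ScreenConfig, screen_htg
from .pathways import cofactor_audit, pathway_completeness
from .synthetic import (
    HIT_TABLE_COLUMNS,
    SimCountParams,
    SimHgtParams,
    make_pathway_fixtures,
    simulate_count_table,
    simulate_hit_table,
)

__all__ = [
    "RunConfig",
    "read_hit_table",
    "write_hit_table",
    "read_count_table",
    "write_tsv",
    "read_config_file",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

_NUMERIC_HIT_COLS = {
    "pident": float, "length": int, "qstart": int, "qend": int,
    "sstart": int, "send": int, "evalue": float, "bitscore": float,
}


@dataclass(frozen=True)
class RunConfig:
    """All thresholds of the pipeline, defaulting to the published values."""

    fdr: float = 0.001
    lfc: float = 1.0
    h: float = 30.0
    bitscore: float = 100.0
    ln_e_ratio: float = -9.0
    fpkm: float = 1.0
    min_ident: float = 99.0
    min_overlap: int = 200
    tophit_identity: float = 40.0
    symbiont_identity: float = 50.0
    seed: int = 0
    out_dir: str = "run"

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            min_h=self.h,
            min_prok_bitscore=self.bitscore,
            max_ln_e_ratio=self.ln_e_ratio,
            min_fpkm=self.fpkm,
            min_tophit_identity=self.tophit_identity,
        )

    def digest(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # output location is not part of the analysis
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig | None) -> str:
    if config is None:
        return f"# symbioscreen v{__version__}"
    return (
        f"# symbioscreen v{__version__} config={config.digest()} seed={config.seed}"
    )


def write_tsv(
    table: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    report_mode: bool = False,
) -> None:
    """Write a header-carrying TSV with a provenance comment line.

    ``report_mode`` rounds float columns half-up to 2 decimals for
    presentation tables; data mode keeps full precision.
    """
    out = table.copy()
    if report_mode:
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].map(lambda v: round_half_up(v, 2))
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_provenance(config) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a transcript count table (transcript_id, length_bp, count_lib1,
    count_lib2); duplicate transcript ids are a format error."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"transcript_id", "length_bp", "count_lib1", "count_lib2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    dup = df["transcript_id"][df["transcript_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate transcript id {dup.iloc[0]!r} in {path}")
    return df


def write_hit_table(hits: pd.DataFrame, path: str | Path,
                    config: RunConfig | None = None) -> None:
    """Write the header-less extended BLAST tabular dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_provenance(config) + "\n")
        hits[HIT_TABLE_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Parse the extended BLAST tabular dialect (12 standard columns plus
    subject_domain and subject_lineage, no header).

    Malformed lines are skipped and logged with their line numbers; the
    count of skipped lines is reported at warning level.
    """
    rows: list[dict] = []
    skipped = 0
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(HIT_TABLE_COLUMNS):
                logger.warning("%s:%d: expected %d columns, got %d - skipped",
                               path, lineno, len(HIT_TABLE_COLUMNS), len(parts))
                skipped += 1
                continue
            record = dict(zip(HIT_TABLE_COLUMNS, parts))
            try:
                for col, typ in _NUMERIC_HIT_COLS.items():
                    record[col] = typ(float(record[col]))
            except ValueError:
                logger.warning("%s:%d: non-numeric field - skipped", path, lineno)
                skipped += 1
                continue
            rows.append(record)
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, skipped)
    if not rows:
        logger.warning("%s: empty hit table", path)
    return pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS)


def read_config_file(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` configuration file into a RunConfig."""
    values: dict[str, object] = {}
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "out_dir":
                values[key] = raw
            elif key in ("seed", "min_overlap"):
                values[key] = int(raw)
            else:
                values[key] = float(raw)
    defaults = RunConfig()
    for key, value in values.items():
        if key not in ("out_dir",) and value != getattr(defaults, key):
            logger.info("config override: %s = %s (default %s)",
                        key, value, getattr(defaults, key))
    return RunConfig(**values)  # type: ignore[arg-type]


def run_full_analysis(config: RunConfig) -> dict:
    """Simulation -> differential expression -> HGT screen -> pathways.

    Writes per-stage TSVs plus a machine-readable ``summary.json`` into
    ``config.out_dir`` and returns the summary.  All randomness flows from
    ``config.seed`` (stage seeds are derived deterministically from it).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: simulate the two-library experiment and call DE
    count_params = SimCountParams(seed=config.seed)
    counts, de_truth = simulate_count_table(count_params)
    libs = LibraryPair(count_params.library_size_1, count_params.library_size_2)
    try:
        de = call_differential(counts, libs, fdr_threshold=config.fdr,
                               lfc_threshold=config.lfc)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"differential-expression stage failed: {exc}") from exc
    write_tsv(counts, out_dir / "counts.tsv", config)
    write_tsv(de, out_dir / "differential_expression.tsv", config)

    # stage 2: simulate a hit table with planted HTGs and screen it
    hit_params = SimHgtParams(seed=config.seed)
    sim = simulate_hit_table(hit_params)
    try:
        verdicts = screen_htg(sim.hits, sim.fpkm, config.screen_config())
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"HGT-screen stage failed: {exc}") from exc
    write_hit_table(sim.hits, out_dir / "hits.tsv", config)
    write_tsv(verdicts, out_dir / "hgt_verdicts.tsv", config)

    retained = verdicts[verdicts["retained"]]["query_id"].tolist()
    planted = sorted(sim.truth[sim.truth == "planted_htg"].index)

    # stage 3: classify the packaged pathway fixtures
    fixtures = make_pathway_fixtures()
    try:
        pathway_verdicts = {
            name: pathway_completeness(list(reactions), fixtures.statuses)
            for name, reactions in fixtures.pathways.items()
        }
        cofactors = cofactor_audit(
            fixtures.cofactor_classes, fixtures.pathways, fixtures.statuses
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pathway stage failed: {exc}") from exc

    report_lines = []
    for name, verdict in sorted(pathway_verdicts.items()):
        report_lines.append(
            f"{name}: {'complete' if verdict.complete else 'incomplete'}"
            + (f" (gaps: {', '.join(verdict.gaps)})" if verdict.gaps else "")
        )
        for a in verdict.assignments:
            providers = ", ".join(f"{o.value}:{g}" for o, g in a.providers) or "-"
            report_lines.append(f"  {a.reaction_id}: {a.provider_class.value} [{providers}]")
    (out_dir / "pathway_report.txt").write_text(
        _provenance(config) + "\n" + "\n".join(report_lines) + "\n", encoding="utf-8"
    )

    summary = {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_transcripts": int(len(counts)),
        "n_enriched_called": int((de["call"] == "enriched").sum()),
        "n_depleted_called": int((de["call"] == "depleted").sum()),
        "n_enriched_true": int((de_truth == "enriched").sum()),
        "n_depleted_true": int((de_truth == "depleted").sum()),
        "n_htg_retained": len(retained),
        "htg_retained": sorted(retained),
        "htg_planted": planted,
        "htg_exact_recovery": sorted(retained) == planted,
        "pathway_verdicts": {
            name: ("complete" if v.complete else "incomplete")
            for name, v in sorted(pathway_verdicts.items())
        },
        "cofactor_providers": cofactors,
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary
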