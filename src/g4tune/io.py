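"""Shared readers/writers and run provenance.

All tabular outputs are CSV/TSV with a single header row preceded by
'#'-prefixed provenance comments (package version, config hash, seed);
sequences go out as 60-column FASTA or GenBank flat files (1-based
inclusive feature coordinates; the in-memory model is 0-based half-open);
fitted models and ground truth as JSON.  Every writer's output is
re-readable by its paired reader.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import __version__
from .activity import ActivityRecord, Context, LinearActivityModel
from .cassette import ExpressionCassette
from .motifs import G4Motif, G4MotifSpec, Level
from .pqs import PQSHit

logger = logging.getLogger("g4tune")


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to stderr (data goes to files/stdout only)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def config_hash(config: Optional[dict]) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(seed: Optional[int] = None, config: Optional[dict] = None) -> List[str]:
    """Provenance header emitted at the top of every tabular output."""
    return [
        f"# g4tune {__version__}",
        f"# config-hash: {config_hash(config)}",
        f"# seed: {seed if seed is not None else 'none'}",
    ]


def _write_table(df: pd.DataFrame, path, seed, config, sep=","):
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False)
    logger.info("wrote %d rows to %s", len(df), path)


def _read_table(path, sep=",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# -- generator configuration (YAML) ---------------------------------------

def load_generator_config(path, seed: Optional[int] = None):
    """Build a :class:`~g4tune.simulate.GeneratorConfig` from a YAML file.

    Top-level keys map to ``GeneratorConfig`` fields; a ``titer_params``
    mapping nests into :class:`~g4tune.simulate.TiterParams`.  A ``--seed``
    given on the command line overrides the file's seed.
    """
    from .simulate import GeneratorConfig, TiterParams

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: generator config must be a mapping")
    if "titer_params" in raw:
        raw["titer_params"] = TiterParams(**raw["titer_params"])
    for key in ("level_offsets", "context_shifts"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = tuple(raw[key].items())
    if seed is not None:
        raw["seed"] = seed
    unknown = set(raw) - set(GeneratorConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown generator-config keys {sorted(unknown)}")
    return GeneratorConfig(**raw)


# -- motif library manifests ----------------------------------------------

def library_manifest(motifs: Sequence[G4Motif], loop_policy: str) -> pd.DataFrame:
    rows = []
    for m in motifs:
        rows.append(
            {
                "label": m.label or "",
                "level": m.spec.level.value,
                "tract_length": m.spec.tract_length,
                "tract_count": m.spec.tract_count,
                "loop_lengths": ";".join(str(l) for l in m.spec.loop_lengths),
                "loop_policy": loop_policy,
                "sequence": m.sequence,
            }
        )
    return pd.DataFrame(rows)


def write_library_csv(motifs, path, loop_policy="balanced", seed=None, config=None):
    _write_table(library_manifest(motifs, loop_policy), path, seed, config)


def read_library_csv(path) -> List[G4Motif]:
    df = _read_table(path)
    out = []
    for _, row in df.iterrows():
        level = Level(row["level"])
        loop_lengths = tuple(int(x) for x in str(row["loop_lengths"]).split(";"))
        spec = G4MotifSpec(level, int(row["tract_length"]), int(row["tract_count"]), loop_lengths)
        seq = str(row["sequence"])
        # recover loop sequences from the realized motif
        loops, pos = [], spec.tract_length
        for n in loop_lengths:
            loops.append(seq[pos:pos + n])
            pos += n + spec.tract_length
        label = str(row["label"]) if row["label"] else None
        out.append(G4Motif(spec, tuple(loops), label))
    return out


def write_fasta(motifs: Sequence[G4Motif], path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=m.label or f"motif_{i+1}", description="")
        for i, m in enumerate(motifs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- PQS hit reports -------------------------------------------------------

def hits_table(seqid: str, hits: Sequence[PQSHit]) -> pd.DataFrame:
    """BED-like table (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "seqid": seqid,
                "start": h.start,
                "end": h.end,
                "score": h.score,
                "tract_length": h.tract_length,
                "tract_starts": ";".join(str(s) for s in h.tract_starts),
                "loop_lengths": ";".join(str(l) for l in h.loop_lengths),
            }
            for h in hits
        ],
        columns=["seqid", "start", "end", "score", "tract_length",
                 "tract_starts", "loop_lengths"],
    )


def write_hits_tsv(tables: Sequence[pd.DataFrame], path, seed=None, config=None):
    df = pd.concat(tables, ignore_index=True) if tables else hits_table("", [])
    _write_table(df, path, seed, config, sep="\t")


# -- activity tables -------------------------------------------------------

def activity_table(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component_label": r.component_label,
                "level": r.level.value,
                "tract_length": r.features[0],
                "tract_count": r.features[1],
                "mean_loop_length": r.features[2],
                "cell_host": r.context.cell_host,
                "format": r.context.format,
                "system": r.context.system,
                "reu_mean": r.reu_mean,
                "reu_sd": r.reu_sd,
                "n_replicates": r.n_replicates,
            }
            for r in records
        ]
    )


def write_activity_csv(records, path, seed=None, config=None):
    _write_table(activity_table(records), path, seed, config)


def read_activity_csv(path) -> List[ActivityRecord]:
    df = _read_table(path)
    return [
        ActivityRecord(
            component_label=str(row["component_label"]),
            level=Level(row["level"]),
            features=(row["tract_length"], row["tract_count"], row["mean_loop_length"]),
            reu_mean=float(row["reu_mean"]),
            reu_sd=float(row["reu_sd"]),
            n_replicates=int(row["n_replicates"]),
            context=Context(
                cell_host=str(row["cell_host"]),
                format=str(row["format"]),
                system=str(row["system"]),
            ),
        )
        for _, row in df.iterrows()
    ]


# -- fitted models ---------------------------------------------------------

def write_model_json(model: LinearActivityModel, path, seed=None, config=None):
    payload = {
        "provenance": {"seed": seed, "config_hash": config_hash(config)},
        "level": model.level.value,
        "intercept": model.intercept,
        "beta_tract_length": model.beta_tract_length,
        "beta_tract_count": model.beta_tract_count,
        "beta_loop_length": model.beta_loop_length,
        "r_squared": model.r_squared,
        "f_pvalue": model.f_pvalue,
        "n": model.n,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model_json(path) -> LinearActivityModel:
    d = json.loads(Path(path).read_text())
    return LinearActivityModel(
        level=Level(d["level"]),
        intercept=d["intercept"],
        beta_tract_length=d["beta_tract_length"],
        beta_tract_count=d["beta_tract_count"],
        beta_loop_length=d["beta_loop_length"],
        r_squared=d["r_squared"],
        f_pvalue=d["f_pvalue"],
        n=d["n"],
    )


# -- cassettes -------------------------------------------------------------

def cassette_record(cassette: ExpressionCassette, name: str = "cassette") -> SeqRecord:
    """GenBank-ready record with one feature per provenance segment."""
    rec = SeqRecord(Seq(cassette.assembled), id=name, name=name[:16],
                    description="g4tune expression cassette")
    rec.annotations["molecule_type"] = "DNA"
    for seg_name, start, end in cassette.segment_map:
        kind = {
            "core_promoter": "promoter",
            "proximal_promoter": "promoter",
            "utr5": "5'UTR",
            "utr3": "3'UTR",
            "cds": "CDS",
        }.get(seg_name, "misc_feature")
        rec.features.append(
            SeqFeature(
                FeatureLocation(start, end, strand=1),
                type=kind,
                qualifiers={"label": [seg_name]},
            )
        )
    return rec


def write_genbank(cassette: ExpressionCassette, path, name: str = "cassette"):
    SeqIO.write([cassette_record(cassette, name)], str(path), "genbank")


def read_genbank_sequence(path) -> str:
    return str(next(SeqIO.parse(str(path), "genbank")).seq)
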