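"""End-to-end interface-conservation analysis with config and provenance.

The orchestrated question: are the residues of a hub subunit (e.g. NFS1)
that contact each partner of the Fe-S assembly supercomplex more conserved
between two homologs than the subunit overall?  Stages: parse the complex
structure, extract each role-pair interface at the distance cutoff, align
the corresponding homolog sequence pair, and compare interface identity with
overall identity.  Reports embed the numeric conventions (cutoff semantics,
identity denominators), input checksums and a config hash, so results are
self-describing and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml
from Bio import SeqIO

import fe_s_conserv
from fe_s_conserv.homologs import (
    SequenceRecord,
    align_pair,
    identity_stats,
    region_identity,
)
from fe_s_conserv.msa import column_profile, map_column_to_reference, read_and_trim, threshold_counts
from fe_s_conserv.structures import contact_residues, parse_structure

__all__ = ["PipelineConfig", "PipelineError", "load_config",
           "run_interface_conservation", "run_report", "read_fasta_record"]

SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def read_fasta_record(path: str | Path) -> SequenceRecord:
    """First record of a FASTA file as a SequenceRecord."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PipelineError("config", f"no FASTA records in {path}")
    rec = records[0]
    return SequenceRecord(id=rec.id, residues=str(rec.seq).upper(),
                          description=rec.description)


@dataclass
class PipelineConfig:
    """Validated configuration for the interface-conservation run."""

    structure: Path
    pairs: list[dict]
    cutoff: float = 4.0
    alignment_mode: str = "local"
    msa: dict | None = None
    output_dir: Path = Path("fe_s_conserv_out")
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; fail before any compute."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise PipelineError("config", "config must be a YAML mapping")
    for key in ("structure", "pairs"):
        if key not in raw:
            raise PipelineError("config", f"missing required key {key!r}")
    structure = Path(raw["structure"])
    if not structure.exists():
        raise PipelineError("config", f"structure file {structure} not found")
    pairs = raw["pairs"]
    if not isinstance(pairs, list) or not pairs:
        raise PipelineError("config", "pairs must be a non-empty list")
    for i, p in enumerate(pairs):
        for key in ("name", "chain_a", "partner", "sequence_a", "sequence_b"):
            if key not in p:
                raise PipelineError("config", f"pairs[{i}] missing key {key!r}")
        for key in ("sequence_a", "sequence_b"):
            if not Path(p[key]).exists():
                raise PipelineError("config", f"pairs[{i}].{key}: "
                                    f"{p[key]} not found")
    msa_cfg = raw.get("msa")
    if msa_cfg is not None:
        for key in ("path", "format", "reference_id"):
            if key not in msa_cfg:
                raise PipelineError("config", f"msa missing key {key!r}")
        if not Path(msa_cfg["path"]).exists():
            raise PipelineError("config", f"msa file {msa_cfg['path']} not found")
    return PipelineConfig(
        structure=structure, pairs=pairs,
        cutoff=float(raw.get("cutoff", 4.0)),
        alignment_mode=str(raw.get("alignment_mode", "local")),
        msa=msa_cfg,
        output_dir=Path(raw.get("output_dir", "fe_s_conserv_out")),
        raw=raw,
    )


def run_interface_conservation(cfg: PipelineConfig,
                               write_outputs: bool = True) -> dict:
    """Interface extraction + homolog identity comparison for each role pair.

    Per pair: the interface residue list of chain_a against the partner,
    the overall identity/similarity of the homolog alignment, the identity
    restricted to the interface positions, and the delta (interface minus
    overall).  Structure residue numbers map to sequence positions via the
    per-pair ``resnum_offset_a`` (sequence position = resnum - offset).
    """
    try:
        structure = parse_structure(cfg.structure)
    except Exception as exc:
        raise PipelineError("parse_structure", str(exc)) from exc

    for i, p in enumerate(cfg.pairs):
        if p["chain_a"] not in structure.chains:
            raise PipelineError("config", f"pairs[{i}].chain_a={p['chain_a']!r} "
                                f"not in structure chains {sorted(structure.chains)}")

    results = []
    failures = []
    for p in cfg.pairs:
        name = p["name"]
        try:
            iface = contact_residues(structure, p["chain_a"], str(p["partner"]),
                                     cutoff=cfg.cutoff)
            seq_a = read_fasta_record(p["sequence_a"])
            seq_b = read_fasta_record(p["sequence_b"])
            aln = align_pair(seq_a, seq_b, mode=cfg.alignment_mode)
            identity, similarity, coverage = identity_stats(aln)
            offset = int(p.get("resnum_offset_a", 0))
            positions = [r.residue_number - offset for r in iface.residues_a
                         if 1 <= r.residue_number - offset <= len(seq_a)]
            entry: dict[str, Any] = {
                "pair": name,
                "chain_a": p["chain_a"], "partner": str(p["partner"]),
                "n_interface_residues": len(iface.residues_a),
                "interface_residues": [str(r) for r in iface.residues_a],
                "overall_identity_pct": identity,
                "overall_similarity_pct": similarity,
                "coverage_pct": coverage,
            }
            if positions:
                report = region_identity(aln, positions, region_name=name)
                entry.update({
                    "interface_identity_pct": report.identity_pct,
                    "interface_similarity_pct": report.similarity_pct,
                    "identity_delta_pct": report.identity_pct - identity,
                    "region_denominator": report.denominator_policy,
                })
            results.append(entry)
        except PipelineError:
            raise
        except Exception as exc:
            failures.append({"pair": name, "stage": "interface_conservation",
                             "error": str(exc)})

    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": fe_s_conserv.__version__,
        "config_hash": cfg.config_hash,
        "input_checksums": {
            str(cfg.structure): _sha256(cfg.structure),
            **{str(Path(p[k])): _sha256(Path(p[k]))
               for p in cfg.pairs for k in ("sequence_a", "sequence_b")},
        },
        "conventions": {
            "cutoff_A": cfg.cutoff,
            "cutoff_semantics": "strict < on heavy-atom pairs",
            "alignment_mode": cfg.alignment_mode,
            "overall_identity_denominator": "aligned_columns",
            "region_identity_denominator": "all_region_positions",
        },
        "pairs": results,
        "failures": failures,
    }

    if cfg.msa is not None:
        try:
            msa = read_and_trim(cfg.msa["path"], cfg.msa["format"],
                                cfg.msa["reference_id"],
                                float(cfg.msa.get("max_gap_fraction", 0.5)))
            profile = column_profile(msa)
            thresholds = tuple(cfg.msa.get("thresholds", (0.5, 0.8, 0.9)))
            counts, absolutes = threshold_counts(profile, thresholds)
            col_to_pos, _ = map_column_to_reference(msa, cfg.msa["reference_id"])
            summary["msa"] = {
                "n_records": msa.n_records, "n_columns": msa.n_columns,
                "threshold_counts": {str(t): c for t, c in counts.items()},
                "absolutely_conserved": [
                    {"column": col, "residue": aa,
                     "reference_position": col_to_pos.get(col)}
                    for col, aa in absolutes],
            }
        except Exception as exc:
            failures.append({"stage": "msa_conservation", "error": str(exc)})

    if write_outputs:
        out = cfg.output_dir
        out.mkdir(parents=True, exist_ok=True)
        stamped = dict(summary)
        stamped["timestamp"] = datetime.now(timezone.utc).isoformat()
        (out / "interface_conservation.json").write_text(
            json.dumps(stamped, indent=2) + "\n")
    return summary


def run_report(stage_outputs: list[dict]) -> dict:
    """Merge schema-valid stage outputs into a single versioned summary."""
    merged: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "stages": []}
    for i, out in enumerate(stage_outputs):
        if not isinstance(out, dict):
            raise ValueError(f"stage output {i} is not a mapping")
        version = out.get("schema_version")
        if version is not None and version != SCHEMA_VERSION:
            raise ValueError(f"stage output {i}: schema_version {version!r} "
                             f"!= {SCHEMA_VERSION!r}")
        merged["stages"].append(out)
    return merged
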