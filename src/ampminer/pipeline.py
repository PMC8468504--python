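"""End-to-end orchestration: generate/load -> ORFs -> mine -> classify ->
derive -> profile -> report bundle.

Every stage writes a TSV into the output directory; a JSON manifest
records the configuration, seed, package version and input checksums so a
run can be reproduced exactly.  All randomness flows from the single seed
in the configuration; two runs with the same config+seed produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .families import DEFAULT_RULES, FamilyRule, classify
from .mining import MiningConfig, mine_precursors
from .orfs import find_orfs
from .peptides import parent_peptide, truncation_series
from .physchem import profile
from .records import read_fasta, write_fasta
from .simulate import PlantSpec, generate_transcriptome, truth_to_frame

logger = logging.getLogger("ampminer")

DEFAULT_PLANTS = (
    PlantSpec("piscidin", 10),
    PlantSpec("defensin", 4),
    PlantSpec("hepcidin", 4),
    PlantSpec("leap2", 4),
    PlantSpec("nklysin", 4),
)


@dataclass
class PipelineConfig:
    """One run's full configuration.

    Exactly one of ``input_fasta`` / ``synthetic`` must be set; ``seed``
    is mandatory for synthetic input.
    """

    out_dir: str
    input_fasta: Optional[str] = None
    synthetic: bool = False
    plants: Sequence[PlantSpec] = DEFAULT_PLANTS
    n_decoys: int = 174
    seed: Optional[int] = None
    mining: MiningConfig = field(default_factory=MiningConfig)
    rules: Sequence[FamilyRule] = DEFAULT_RULES
    min_aa: int = 50
    ph: float = 7.0
    parent_len: int = 20
    log_level: str = "INFO"

    def validate(self) -> None:
        if bool(self.input_fasta) == bool(self.synthetic):
            raise ValueError(
                "exactly one of input_fasta / synthetic must be given")
        if self.synthetic and self.seed is None:
            raise ValueError("seed is mandatory for synthetic input")


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage, write the report bundle, return its file map."""
    cfg.validate()
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level,
                        format="%(name)s %(levelname)s %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    stage = "input"
    try:
        if cfg.synthetic:
            records, truth = generate_transcriptome(
                list(cfg.plants), cfg.n_decoys, seed=cfg.seed)
            fasta = out / "transcripts.fasta"
            write_fasta(records, fasta)
            truth_to_frame(truth).to_csv(out / "ground_truth.tsv",
                                         sep="\t", index=False)
            bundle["transcripts"] = fasta
            bundle["ground_truth"] = out / "ground_truth.tsv"
        else:
            records = read_fasta(cfg.input_fasta, "nucleotide")
            fasta = Path(cfg.input_fasta)
        logger.info("[input] %d transcripts", len(records))

        stage = "orfs"
        orfs = [o for t in records for o in find_orfs(t, min_aa=cfg.min_aa)]
        logger.info("[orfs] %d ORFs (min %d aa)", len(orfs), cfg.min_aa)

        stage = "mine"
        candidates = mine_precursors(orfs, cfg.mining)
        cand_rows = [{
            "transcript_id": c.orf.transcript_id,
            "start": c.orf.start, "end": c.orf.end,
            "strand": c.orf.strand, "frame": c.orf.frame,
            "track": c.track,
            "motif_hits": ";".join(f"{m}@{p}" for m, p in c.motif_hits),
            "signal_cleavage": ("" if c.signal_cleavage is None
                                else c.signal_cleavage),
            "mature_preview": c.mature_region[:25],
        } for c in candidates]
        pd.DataFrame(cand_rows, columns=[
            "transcript_id", "start", "end", "strand", "frame", "track",
            "motif_hits", "signal_cleavage", "mature_preview",
        ]).to_csv(out / "candidates.tsv", sep="\t", index=False)
        bundle["candidates"] = out / "candidates.tsv"
        logger.info("[mine] %d candidates", len(candidates))

        stage = "classify"
        calls = [classify(c, tuple(cfg.rules)) for c in candidates]
        pd.DataFrame([{
            "transcript_id": fc.candidate.orf.transcript_id,
            "family": fc.family,
            "evidence": ";".join(fc.evidence),
            "mature_start": "" if fc.mature_start is None else fc.mature_start,
            "mature_end": "" if fc.mature_end is None else fc.mature_end,
        } for fc in calls], columns=[
            "transcript_id", "family", "evidence", "mature_start",
            "mature_end",
        ]).to_csv(out / "families.tsv", sep="\t", index=False)
        bundle["families"] = out / "families.tsv"

        stage = "derive"
        peptides = []
        for fc in calls:
            c = fc.candidate
            if (fc.family == "piscidin_like"
                    and c.signal_cleavage is not None
                    and len(c.protein) >= c.signal_cleavage + cfg.parent_len):
                parent = parent_peptide(
                    c.protein, c.signal_cleavage, cfg.parent_len,
                    id_prefix=f"{c.orf.transcript_id}_pep")
                peptides.extend(truncation_series(parent))
            elif fc.family in ("hepcidin", "leap2", "defensin", "nklysin"):
                seq = fc.mature_seq
                if seq:
                    from .peptides import PeptideCandidate
                    peptides.append(PeptideCandidate(
                        id=f"{c.orf.transcript_id}_mature", seq=seq,
                        parent_id=c.orf.transcript_id,
                        rule="convertase_mature"))
        pd.DataFrame([{
            "id": p.id, "parent_id": p.parent_id, "rule": p.rule,
            "sequence": p.seq, "length": len(p.seq),
        } for p in peptides], columns=[
            "id", "parent_id", "rule", "sequence", "length",
        ]).to_csv(out / "peptides.tsv", sep="\t", index=False)
        bundle["peptides"] = out / "peptides.tsv"
        logger.info("[derive] %d peptides", len(peptides))

        stage = "physchem"
        bundle["physchem"] = out / "physchem.tsv"
        physchem_table(
            [(p.id, p.seq, p.cterm_amidated) for p in peptides], ph=cfg.ph
        ).to_csv(bundle["physchem"], sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": _config_dict(cfg),
            "inputs": {fasta.name: _sha256(fasta)} if fasta.exists() else {},
            "outputs": {k: v.name for k, v in bundle.items()},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        bundle["manifest"] = out / "manifest.json"
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err
    return bundle


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("out_dir")  # location-independent: bundles compare by content
    d["plants"] = [dataclasses.asdict(p) for p in cfg.plants]
    d["rules"] = [dataclasses.asdict(r) for r in cfg.rules]
    return d


def physchem_table(peptides: Sequence[tuple[str, str, bool]],
                   ph: float = 7.0) -> pd.DataFrame:
    """Full-precision property table for (id, seq, amidated) peptides."""
    rows = []
    for pid, seq, amidated in peptides:
        pr = profile(seq, pH=ph, cterm_amidated=amidated)
        rows.append({
            "id": pid, "sequence": seq, "n": pr.length,
            "avg_mass": round(pr.avg_mass, 4),
            "mono_mass": round(pr.mono_mass, 5),
            "net_charge": pr.formal_charge,
            "charge_at_pH": round(pr.ph_charge, 4),
            "pH": ph, "pI": round(pr.pI, 3),
            "hydrophobic_ratio": round(pr.hydrophobic_ratio, 4),
            "H_fp": round(pr.H_fp, 4),
            "mu_H": round(pr.mu_H, 4),
            "charged_face_angle": pr.wheel.charged_face_angle,
            "hydrophobic_face_angle": pr.wheel.hydrophobic_face_angle,
        })
    return pd.DataFrame(rows, columns=[
        "id", "sequence", "n", "avg_mass", "mono_mass", "net_charge",
        "charge_at_pH", "pH", "pI", "hydrophobic_ratio", "H_fp", "mu_H",
        "charged_face_angle", "hydrophobic_face_angle"])


def table1_report(parents: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Design-table view: each 20-mer parent and its monobasic series.

    For every (name prefix, parent sequence) pair, regenerates the
    truncation series and reports id, sequence, length, nearest-Da average
    mass, formal net charge and nearest-percent hydrophobic ratio — the
    grid used to pick synthesis candidates.
    """
    rows = []
    for prefix, seq in parents:
        parent = parent_peptide(seq, 0, len(seq), id_prefix=prefix)
        series = truncation_series(parent)
        if len(series) == 1:
            logger.warning("parent %s has no monobasic truncation sites",
                           prefix)
        for p in series:
            pr = profile(p.seq, cterm_amidated=p.cterm_amidated)
            rows.append({
                "id": p.id, "sequence": p.seq, "n": pr.length,
                "mw_da": pr.avg_mass_da, "net_charge": pr.formal_charge,
                "hydrophobicity_pct": pr.hydrophobic_pct,
            })
    return pd.DataFrame(rows, columns=[
        "id", "sequence", "n", "mw_da", "net_charge", "hydrophobicity_pct"])
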