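"""End-to-end orchestration: configuration, the genomics track and the
phenomics track.

Both tracks share one configuration (YAML key-value file or
:class:`RunConfig` built in code) but run independently.  All output
files are written atomically (temp file + rename) so a failed run never
leaves a partially written table, and every run drops a JSON manifest
recording the configuration hash, package version and accumulated
warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml
from Bio.Seq import Seq

from . import __version__
from .align_io import AlignmentSegment, anchor_align, filter_segments, read_segments, transpose_segments
from .annotation import CdsRecord, read_gff3
from .genome import Genome
from .pangenome import (
    ProteinRecord,
    category_summary,
    cluster_cds,
    pathway_completeness,
    read_pathways,
    venn_partition,
)
from .pm_compare import delta_a_classify, ec_association, load_ec_map, scatter_table
from .pm_kinetics import activity, categorize_activities, curve_parameters, normalize_heatmap, read_kinetics
from .synteny import order_conservation
from .uniqueness import similarity_matrix, unique_regions, uniqueness_report

logger = logging.getLogger("straincomp")

__all__ = ["RunConfig", "run_genomics", "run_phenomics"]


@dataclass
class RunConfig:
    # genomics track
    genome_fastas: Dict[str, str] = field(default_factory=dict)  # genome id -> FASTA
    gff3_paths: Dict[str, str] = field(default_factory=dict)  # genome id -> GFF3
    segments_path: Optional[str] = None  # external segments; None -> built-in aligner
    segments_format: str = "tsv"
    aligner_k: int = 15
    aligner_max_gap: int = 100
    min_segment_len: int = 300
    min_unique_len: int = 300
    synteny_mode: str = "strict_rank"
    cluster_min_identity: float = 0.5
    cluster_min_coverage: float = 0.5
    pathways_path: Optional[str] = None
    # phenomics track
    kinetics_csv: Optional[str] = None
    kinetics_manifest: Optional[str] = None
    cutpoints: Tuple[float, float, float] = (0.25, 0.50, 0.75)
    consistency_tol: float = 0.25
    delta_centering: str = "zero"
    ec_map_path: Optional[str] = None
    # shared
    outdir: str = "straincomp_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cutpoints" in raw:
            raw["cutpoints"] = tuple(raw["cutpoints"])
        return cls(**raw)

    def validate_genomics(self) -> None:
        if not self.genome_fastas:
            raise ValueError("no genomes configured")
        if len(set(self.genome_fastas)) != len(self.genome_fastas):
            raise ValueError("genome ids must be unique")
        for gid, path in self.genome_fastas.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"genome {gid!r}: missing FASTA {path}")
        for gid, path in self.gff3_paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"genome {gid!r}: missing GFF3 {path}")
        if self.min_segment_len < 0 or self.min_unique_len < 0:
            raise ValueError("length thresholds must be >= 0")

    def validate_phenomics(self) -> None:
        if not self.kinetics_csv:
            raise ValueError("no kinetics CSV configured")
        if not Path(self.kinetics_csv).exists():
            raise FileNotFoundError(f"missing kinetics CSV {self.kinetics_csv}")
        if self.kinetics_manifest and not Path(self.kinetics_manifest).exists():
            raise FileNotFoundError(f"missing manifest {self.kinetics_manifest}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            default=str, sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_df(path: Path, df: pd.DataFrame, **kwargs) -> None:
    _atomic_write_text(path, df.to_csv(sep="\t", **kwargs))


def _write_manifest(outdir: Path, config: RunConfig, outputs: List[str],
                    warnings: Dict[str, int], track: str) -> None:
    manifest = {
        "track": track,
        "straincomp_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": outputs,
        "warnings": warnings,
    }
    _atomic_write_text(outdir / f"manifest_{track}.json", json.dumps(manifest, indent=2))


def _translate(genome: Genome, cds: CdsRecord) -> str:
    seq = genome.replicons[cds.replicon][cds.start : cds.end]
    if cds.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return str(Seq(seq).translate(table=11)).rstrip("*")


def _pairwise_segments(
    config: RunConfig, genomes: List[Genome]
) -> Dict[Tuple[str, str], List[AlignmentSegment]]:
    ids = [g.genome_id for g in genomes]
    by_id = {g.genome_id: g for g in genomes}
    pairs: Dict[Tuple[str, str], List[AlignmentSegment]] = {}
    if config.segments_path:
        segs = read_segments(config.segments_path, config.segments_format)
        for s in segs:
            pairs.setdefault((s.query_genome, s.target_genome), []).append(s)
    else:
        for i, gi in enumerate(ids):
            for gj in ids[i + 1 :]:
                fwd = anchor_align(
                    by_id[gi], by_id[gj],
                    k=config.aligner_k, max_gap=config.aligner_max_gap,
                    min_chain=config.min_segment_len,
                )
                pairs[(gi, gj)] = fwd
                pairs[(gj, gi)] = transpose_segments(fwd)
    return {
        pair: filter_segments(segs, config.min_segment_len)
        for pair, segs in pairs.items()
    }


def run_genomics(config: RunConfig) -> Dict[str, Path]:
    """Run the genome-comparison track; returns paths of written outputs."""
    config.validate_genomics()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: Dict[str, int] = {}

    genomes = [Genome.from_fasta(gid, p) for gid, p in config.genome_fastas.items()]
    by_id = {g.genome_id: g for g in genomes}
    ids = list(by_id)
    annotations: Dict[str, List[CdsRecord]] = {
        gid: read_gff3(p) for gid, p in config.gff3_paths.items()
    }

    logger.info("aligning %d genomes pairwise", len(genomes))
    pairs = _pairwise_segments(config, genomes)
    outputs: Dict[str, Path] = {}

    sim = similarity_matrix(pairs, genomes)
    outputs["similarity"] = outdir / "similarity_matrix.tsv"
    _atomic_write_df(outputs["similarity"], sim, na_rep="-")

    report_rows = []
    for gid in ids:
        segs = [s for (qi, _), ss in pairs.items() if qi == gid for s in ss]
        uniq = unique_regions(by_id[gid], segs, config.min_unique_len)
        bed = outdir / f"unique_regions_{gid}.bed"
        uniq.to_bed(bed)
        outputs[f"unique_bed_{gid}"] = bed
        if gid in annotations:
            report_rows.append(uniqueness_report(uniq, annotations[gid], by_id[gid]).to_series())
        else:
            logger.warning("no GFF3 for %s; uniqueness report row limited", gid)
            warnings["missing_gff3"] = warnings.get("missing_gff3", 0) + 1
            report_rows.append(
                uniqueness_report(uniq, [], by_id[gid]).to_series()
            )
    outputs["uniqueness_report"] = outdir / "uniqueness_report.tsv"
    _atomic_write_df(outputs["uniqueness_report"], pd.DataFrame(report_rows).T)

    oc_rows = []
    for i, gi in enumerate(ids):
        for gj in ids[i + 1 :]:
            oc = order_conservation(
                pairs.get((gi, gj), []),
                by_id[gi].replicon_order, by_id[gj].replicon_order,
                mode=config.synteny_mode,
            )
            oc_rows.append(
                {"genome_a": gi, "genome_b": gj, "conserved": oc.n_same_order,
                 "total": oc.n_total, "pct": oc.pct, "cell": oc.cell()}
            )
    outputs["order_conservation"] = outdir / "order_conservation.tsv"
    _atomic_write_df(outputs["order_conservation"], pd.DataFrame(oc_rows), index=False)

    proteins = [
        ProteinRecord(gid, cds.cds_id, _translate(by_id[gid], cds))
        for gid, recs in annotations.items()
        for cds in recs
    ]
    clusters = cluster_cds(
        proteins, config.cluster_min_identity, config.cluster_min_coverage
    )
    venn = venn_partition(clusters, list(annotations) or ids)
    outputs["venn"] = outdir / "venn_partition.json"
    _atomic_write_text(outputs["venn"], json.dumps(venn.to_json_dict(), indent=2))

    cats = category_summary([c for recs in annotations.values() for c in recs])
    outputs["category_summary"] = outdir / "category_summary.tsv"
    _atomic_write_df(outputs["category_summary"], cats.to_frame("count"))

    if config.pathways_path:
        pathways = read_pathways(config.pathways_path)
        pw_rows = []
        for gid in ids:
            ecs = {ec for c in annotations.get(gid, []) for ec in c.ec_numbers}
            complete, near = pathway_completeness(pathways, ecs)
            pw_rows.append(
                {"genome": gid, "fraction_complete": complete, "fraction_all_but_one": near}
            )
        outputs["pathway_completeness"] = outdir / "pathway_completeness.tsv"
        _atomic_write_df(outputs["pathway_completeness"], pd.DataFrame(pw_rows), index=False)
    else:
        logger.info("no pathway definitions configured; completeness table skipped")

    _write_manifest(outdir, config, [str(p) for p in outputs.values()], warnings, "genomics")
    return outputs


def run_phenomics(config: RunConfig) -> Dict[str, Path]:
    """Run the phenotype-microarray track; returns paths of written outputs."""
    config.validate_phenomics()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: Dict[str, int] = {}

    curves = read_kinetics(config.kinetics_csv, config.kinetics_manifest, warnings)
    if not curves:
        raise ValueError("kinetics file contains no well columns")

    param_rows = []
    for c in curves:
        row = {"strain_id": c.strain_id, "plate_id": c.plate_id, "well_id": c.well_id,
               "substrate": c.substrate, "replicate": c.replicate}
        row.update(curve_parameters(c).as_dict())
        param_rows.append(row)
    outputs: Dict[str, Path] = {}
    outputs["curve_parameters"] = outdir / "curve_parameters.tsv"
    _atomic_write_df(outputs["curve_parameters"], pd.DataFrame(param_rows), index=False)

    grouped: Dict[Tuple[str, str, str], List] = {}
    for c in curves:
        grouped.setdefault((c.strain_id, c.plate_id, c.substrate), []).append(c)
    records = {key: activity(cs, config.consistency_tol) for key, cs in grouped.items()}

    # per-plate, per-strain four-level categorization
    plates: Dict[Tuple[str, str], Dict[str, float]] = {}
    for (strain, plate, substrate), rec in records.items():
        plates.setdefault((strain, plate), {})[substrate] = rec.activity
    for (strain, plate), acts in plates.items():
        levels = categorize_activities(acts, config.cutpoints)
        for substrate, level in levels.items():
            records[(strain, plate, substrate)].level = level

    act_rows = [
        {"strain_id": r.strain_id, "plate_id": r.plate_id, "well_id": r.well_id,
         "substrate": r.substrate, "activity": r.activity, "level": r.level,
         "consistent": r.consistent}
        for r in records.values()
    ]
    n_inconsistent = sum(not r.consistent for r in records.values())
    if n_inconsistent:
        warnings["inconsistent_replicates"] = n_inconsistent
        logger.warning("%d strain x substrate activities flagged inconsistent", n_inconsistent)
    outputs["activity"] = outdir / "activity.tsv"
    _atomic_write_df(outputs["activity"], pd.DataFrame(act_rows), index=False)

    # heat-map matrix: per-plate min-max normalized activities
    hm_rows = []
    for (strain, plate), acts in plates.items():
        subs = list(acts)
        norm = normalize_heatmap([acts[s] for s in subs])
        for s, v in zip(subs, norm):
            hm_rows.append({"plate_id": plate, "substrate": s, "strain_id": strain,
                            "normalized_activity": float(v)})
    outputs["heatmap"] = outdir / "heatmap.tsv"
    _atomic_write_df(outputs["heatmap"], pd.DataFrame(hm_rows), index=False)

    strains = sorted({c.strain_id for c in curves})
    if len(strains) == 2:
        s1, s2 = strains
        acts1 = {sub: rec.activity for (st, _, sub), rec in sorted(records.items()) if st == s1}
        acts2 = {sub: rec.activity for (st, _, sub), rec in sorted(records.items()) if st == s2}
        common = [s for s in acts1 if s in acts2]
        results = delta_a_classify(
            {s: acts1[s] for s in common}, {s: acts2[s] for s in common},
            centering=config.delta_centering,
        )
        df, offsets = scatter_table(results)
        delta_df = pd.DataFrame(
            [{"substrate": r.substrate, "a_strain1": r.a_strain1, "a_strain2": r.a_strain2,
              "delta_a": r.delta_a, "mu_a": r.mu_a, "sigma_a": r.sigma_a, "call": r.call}
             for r in results]
        )
        outputs["delta_a"] = outdir / "delta_a.tsv"
        _atomic_write_df(outputs["delta_a"], delta_df, index=False)
        outputs["scatter"] = outdir / "scatter_table.tsv"
        scatter_txt = df.to_csv(sep="\t", index=False)
        scatter_txt += "".join(f"# {k}\t{v:.6g}\n" for k, v in offsets.items())
        _atomic_write_text(outputs["scatter"], scatter_txt)
    else:
        logger.info("ΔA stage skipped: %d strain(s) present, need exactly 2", len(strains))

    mapping = load_ec_map(config.ec_map_path) if config.ec_map_path else None
    substrates = sorted({c.substrate for c in curves})
    assoc = ec_association(substrates, mapping)
    assoc_df = pd.DataFrame(
        [{"substrate": a.substrate,
          "ec_codes": a.ec_codes if isinstance(a.ec_codes, str) else ";".join(a.ec_codes)}
         for a in assoc]
    )
    outputs["ec_association"] = outdir / "ec_association.tsv"
    _atomic_write_df(outputs["ec_association"], assoc_df, index=False)

    _write_manifest(outdir, config, [str(p) for p in outputs.values()], warnings, "phenomics")
    return outputs
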