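"""Pipeline orchestration: configuration, staged execution, manifests.

``run_pipeline`` chains the stages — LD profiles per lead, candidate
sets, cross-trait intersection, motif annotation of the shared
candidates, and (optionally) the isoform-ratio genotype test — writing
per-stage TSV/JSON outputs plus a manifest with input hashes, the
configuration and the seed, so a run is a pure function of
(inputs, config, seed) and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import genotype_io, isoforms, ld, mapper, motifs

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; validated before any compute."""

    vcf: str
    sample_map: str
    lead_list: str
    fasta: str | None = None
    region: str | None = None  # chrom:start-end
    r2_threshold: float = 0.2
    populations: tuple[str, ...] = ()
    motif_list: str | None = None  # TSV; default Rbfox GCATG when None
    context_halfwidth: int = 8
    abundance_table: str | None = None
    risk_genotype: str = "AA"
    nonrisk_genotype: str = "TT"
    seed: int = 0
    out_dir: str = "crossld_run"


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    for name in ("vcf", "sample_map", "lead_list"):
        path = getattr(cfg, name)
        if not path:
            problems.append(f"{name}: required input path missing")
        elif not Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    for name in ("fasta", "motif_list", "abundance_table"):
        path = getattr(cfg, name)
        if path and not Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    if not 0 < cfg.r2_threshold < 1:
        problems.append(
            f"r2_threshold out of (0,1): {cfg.r2_threshold}; choose a value "
            "strictly between 0 and 1"
        )
    if cfg.region:
        try:
            genotype_io.parse_region(cfg.region)
        except ValueError as exc:
            problems.append(f"region: {exc}")
    if cfg.context_halfwidth < 4:
        problems.append("context_halfwidth: must be >= 4 to fit the motif")
    return problems


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, out: Path) -> None:
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "input_hashes": {
            name: _sha256(p)
            for name in (
                "vcf", "sample_map", "lead_list", "fasta",
                "motif_list", "abundance_table",
            )
            if (p := getattr(cfg, name))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; return the run directory.

    On a stage failure, partial outputs are kept and a FAILED marker
    file naming the stage and error is written before re-raising.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        _write_manifest(cfg, out)

        stage = "load"
        samples = genotype_io.read_sample_map(cfg.sample_map)
        g = genotype_io.read_vcf(cfg.vcf, region=cfg.region, samples=samples)
        leads = mapper.read_lead_list(cfg.lead_list)
        pops = cfg.populations or tuple(
            sorted(set(samples.population.values()))
        )

        stage = "haplotypes"
        h_all = genotype_io.to_haplotypes(g)
        keep = [i for i, p in enumerate(h_all.source_populations) if p in pops]
        pooled = genotype_io.HaplotypeMatrix(
            h_all.variants,
            h_all.haplotypes[keep],
            [h_all.source_populations[i] for i in keep],
        )

        stage = "ld_profiles"
        profiles: dict[str, ld.LDProfile] = {}
        for lead in leads:
            try:
                pooled.variant_index(lead.rsid)
            except KeyError:
                raise ValueError(
                    f"lead variant {lead.rsid!r} absent from the genotype "
                    "panel; refusing to proxy-substitute"
                ) from None
            profile = ld.ld_profile(pooled, lead.rsid)
            profiles[lead.rsid] = profile
            ld.write_ld_profile(
                profile, str(out / f"ld_profile.{lead.rsid}.tsv")
            )

        stage = "intersection"
        cfg_map = mapper.MapperConfig(r2_threshold=cfg.r2_threshold)
        sets = {
            rsid: mapper.candidate_set(p, cfg_map)
            for rsid, p in profiles.items()
        }
        result = mapper.intersect_candidates(sets)
        mapper.shared_ld_table(
            result,
            tsv_path=str(out / "shared_table.tsv"),
            json_path=str(out / "shared_table.json"),
        )

        stage = "motif_annotation"
        motif_rows = []
        if cfg.fasta:
            motif_defs = (
                motifs.read_motif_list(cfg.motif_list)
                if cfg.motif_list
                else [motifs.MotifDef()]
            )
            half = cfg.context_halfwidth
            by_id = {v.id: v for v in pooled.variants}
            for vid in result.shared:
                v = by_id[vid]
                seq = genotype_io.read_fasta_context(
                    cfg.fasta, v.chrom, v.pos - half, v.pos + half
                )
                ctx = motifs.AlleleContext(seq, half, v.ref, v.alt)
                for hit in motifs.scan_motifs(ctx, motif_defs):
                    motif_rows.append(
                        {
                            "variant_id": vid,
                            "motif": hit.motif,
                            "strand": hit.strand,
                            "variant_offset_in_motif": (
                                hit.variant_offset_in_motif
                            ),
                            "status": hit.status,
                        }
                    )
            import pandas as pd

            pd.DataFrame(
                motif_rows,
                columns=[
                    "variant_id", "motif", "strand",
                    "variant_offset_in_motif", "status",
                ],
            ).to_csv(out / "motif_annotation.tsv", sep="\t", index=False)

        stage = "isoform_test"
        isoform_report = None
        if cfg.abundance_table:
            table = isoforms.read_abundance_table(cfg.abundance_table)
            comp = isoforms.compare_ratio_by_genotype(
                table, cfg.risk_genotype, cfg.nonrisk_genotype
            )
            total = isoforms.total_expression_test(
                table, cfg.risk_genotype, cfg.nonrisk_genotype
            )
            isoform_report = {
                "ratio_test": {
                    "U": comp.U,
                    "p_two_sided": comp.p_two_sided,
                    "method": comp.method,
                    "n": [comp.n_a, comp.n_b],
                },
                "total_expression_test": {
                    "U": total.U,
                    "p_two_sided": total.p_two_sided,
                    "method": total.method,
                },
            }
            with open(out / "isoform_test.json", "w") as fh:
                json.dump(isoform_report, fh, indent=2)

        stage = "report"
        report = {
            "n_variants": g.n_variants,
            "n_skipped_records": g.n_skipped,
            "n_haplotypes": pooled.n_haplotypes,
            "populations": list(pops),
            "leads": [lead.rsid for lead in leads],
            "per_lead_candidate_counts": {
                rsid: len(cs.entries) for rsid, cs in sets.items()
            },
            "shared_variants": result.shared,
            "motif_annotation": motif_rows,
            "isoform_test": isoform_report,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
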