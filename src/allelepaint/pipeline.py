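"""Configuration-driven end-to-end runs.

Stages: ingest -> diagnostics -> painting -> summaries -> divergence ->
(tree branch counts) -> (enrichment), with the last two only when their
inputs are configured.  Each output table carries ``# key=value`` header
comments naming the thresholds and modes used, and a manifest records
versions, input digests, and warning counts so that silent data loss is
impossible.  Re-running an identical config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd

from . import io as apio
from .diagnostics import find_diagnostic_sites, fitch_ancestral
from .divergence import (
    branch_omega_screen,
    branch_substitutions,
    ng86_dnds,
    pairwise_divergence,
    similarity_matrix,
)
from .errors import ConfigError, FormatError
from .model import DiagnosticSiteSet, GENOTYPE_CATEGORIES
from .painting import (
    classify_panel,
    haplotype_catalog,
    paint_haplotype,
    summarize_lineages,
    summary_frame,
)
from .structure import (
    StructureAnnotation,
    enrichment_test,
    ligand_binding_sites,
    load_poses,
    load_residue_coordinates,
    map_substitutions_to_segments,
    read_tm_segments,
)

log = logging.getLogger(__name__)

_MAX_SIMILARITY_SEQS = 60


@dataclass
class RunConfig:
    # inputs
    haplotype_fasta: str = ""
    vcf: str = ""
    reference_fasta: str = ""
    metadata: str = ""
    tree: str = ""
    outgroup: str = ""
    structure_pdb: str = ""
    poses: list[str] = field(default_factory=list)
    tm_segments: str = ""
    # clade definition: reference-haplotype name lists OR precomputed sites
    clade_I_refs: str = ""
    clade_II_refs: str = ""
    diagnostic_sites: str = ""
    # thresholds / modes
    gene: str = "gene"
    fixation_threshold: float = 1.0
    cutoff: float = 5.0
    sidedness: str = "two-sided"
    binding_mode: str = "intersection"
    divergence_denominator: str = "pairwise"
    trailing_bases: int = 0
    # run
    outdir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if not self.metadata:
            raise ConfigError("metadata path is required")
        if not self.haplotype_fasta and not self.vcf:
            raise ConfigError("either haplotype_fasta or vcf is required")
        if self.vcf and not self.reference_fasta:
            raise ConfigError("vcf input requires reference_fasta")
        if not self.diagnostic_sites and not (
            self.clade_I_refs and self.clade_II_refs
        ):
            raise ConfigError(
                "clade definition required: clade_I_refs + clade_II_refs, "
                "or a precomputed diagnostic_sites table"
            )
        if not 0.5 < self.fixation_threshold <= 1.0:
            raise ConfigError("fixation_threshold must be in (0.5, 1.0]")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        if self.sidedness not in ("two-sided", "one-sided"):
            raise ConfigError("sidedness must be two-sided or one-sided")
        if self.binding_mode not in ("intersection", "union"):
            raise ConfigError("binding_mode must be intersection or union")
        if self.divergence_denominator not in ("pairwise", "full_cds"):
            raise ConfigError("divergence_denominator must be pairwise or full_cds")
        for name in (
            "haplotype_fasta", "vcf", "reference_fasta", "metadata", "tree",
            "structure_pdb", "tm_segments", "clade_I_refs", "clade_II_refs",
            "diagnostic_sites",
        ):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        for p in self.poses:
            if not Path(p).exists():
                raise ConfigError(f"pose path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"bad config line: {raw!r}")
            key, val = line.split("=", 1)
            kv[key.strip()] = val.strip()
        cfg = cls()
        for key, val in kv.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(val))
            elif isinstance(current, float):
                setattr(cfg, key, float(val))
            elif isinstance(current, list):
                setattr(cfg, key, [p for p in val.split(";") if p])
            else:
                setattr(cfg, key, val)
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, params: dict) -> None:
    with open(path, "w") as fh:
        for key, val in params.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_name_list(path: str | Path) -> list[str]:
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not names:
        raise FormatError(f"empty reference list {path}")
    return names


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1
        if len(self.messages) < 100:
            self.messages.append(record.getMessage())


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counter = _WarningCounter()
    root_logger = logging.getLogger("allelepaint")
    root_logger.addHandler(counter)
    try:
        manifest = _run_stages(config, outdir)
    finally:
        root_logger.removeHandler(counter)
    manifest["warnings"] = {"count": counter.count, "messages": counter.messages}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_stages(config: RunConfig, outdir: Path) -> dict:
    params = {
        "gene": config.gene,
        "fixation_threshold": config.fixation_threshold,
        "divergence_denominator": config.divergence_denominator,
        "binding_mode": config.binding_mode,
        "cutoff_A": config.cutoff,
        "sidedness": config.sidedness,
        "seed": config.seed,
    }
    import Bio
    import numpy
    import pandas
    import scipy

    manifest: dict = {
        "package": "allelepaint",
        "version": _pkg_version("allelepaint"),
        "library_versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "biopython": Bio.__version__,
        },
        "parameters": dict(params),
        "inputs": {},
        "stages": [],
        "outputs": {},
    }
    for name in (
        "haplotype_fasta", "vcf", "reference_fasta", "metadata", "tree",
        "structure_pdb", "tm_segments", "clade_I_refs", "clade_II_refs",
        "diagnostic_sites",
    ):
        p = getattr(config, name)
        if p:
            manifest["inputs"][name] = {"path": p, "sha256": _sha256(p)}
    for i, p in enumerate(config.poses):
        manifest["inputs"][f"pose_{i}"] = {"path": p, "sha256": _sha256(p)}

    # ingest ---------------------------------------------------------------
    if config.haplotype_fasta:
        haplotypes = apio.read_haplotype_fasta(
            config.haplotype_fasta, config.metadata, config.trailing_bases
        )
    else:
        from Bio import SeqIO

        ref = str(next(SeqIO.parse(config.reference_fasta, "fasta")).seq)
        haplotypes = apio.read_vcf_to_haplotypes(
            config.vcf, ref, config.metadata, config.trailing_bases
        )
    metadata = apio.read_metadata(config.metadata)
    manifest["stages"].append("ingest")
    manifest["n_haplotypes"] = len(haplotypes)
    manifest["n_samples"] = len({h.sample_id for h in haplotypes})

    # diagnostics ----------------------------------------------------------
    if config.diagnostic_sites:
        df = pd.read_csv(config.diagnostic_sites, sep="\t", comment="#")
        sites = DiagnosticSiteSet.from_frame(df, gene=config.gene)
    else:
        clade_I = apio.partition_by_names(
            haplotypes, _read_name_list(config.clade_I_refs)
        )
        clade_II = apio.partition_by_names(
            haplotypes, _read_name_list(config.clade_II_refs)
        )
        sites = find_diagnostic_sites(
            clade_I, clade_II, config.fixation_threshold, gene=config.gene
        )
    _write_tsv(sites.to_frame(), outdir / "diagnostic_sites.tsv", params)
    manifest["stages"].append("diagnostics")
    manifest["n_diagnostic_sites"] = len(sites)
    manifest["n_nonsynonymous_sites"] = sum(s.is_nonsynonymous for s in sites)
    manifest["outputs"]["diagnostic_sites"] = "diagnostic_sites.tsv"

    # painting -------------------------------------------------------------
    phased = [h for h in haplotypes if h.phase in (1, 2)]
    paintings = [paint_haplotype(h, sites) for h in phased]
    paint_df = pd.DataFrame(
        {
            "haplotype": [p.name for p in paintings],
            "states": [p.states for p in paintings],
            "category": [p.category for p in paintings],
            "min_crossovers": [p.min_crossovers for p in paintings],
            "n_third_allele": [p.n_third_allele for p in paintings],
        }
    )
    _write_tsv(paint_df, outdir / "paintings.tsv", params)
    classifications = classify_panel(haplotypes, sites)
    class_df = pd.DataFrame(
        {
            "sample_id": list(classifications),
            "lineage": [metadata[s].lineage for s in classifications],
            "category": list(classifications.values()),
        }
    )
    _write_tsv(class_df, outdir / "classifications.tsv", params)
    manifest["stages"].append("painting")
    manifest["outputs"]["paintings"] = "paintings.tsv"
    manifest["outputs"]["classifications"] = "classifications.tsv"

    # summaries ------------------------------------------------------------
    summaries = summarize_lineages(classifications, metadata)
    sdf = summary_frame(summaries)
    headline = sdf.copy()
    for col in headline.columns:
        if col.startswith("pct_"):
            # headline table rounds to whole percent (round-half-even)
            headline[col] = headline[col].round(0).astype(int)
    _write_tsv(headline, outdir / "lineage_summary.tsv", params)
    sdf.to_json(outdir / "lineage_summary.json", orient="records", indent=1)
    lineage_of = {s: m.lineage for s, m in metadata.items()}
    catalog = haplotype_catalog(paintings, lineage_of)
    _write_tsv(catalog, outdir / "haplotype_catalog.tsv", params)
    manifest["stages"].append("summaries")
    manifest["outputs"]["lineage_summary"] = "lineage_summary.tsv"
    manifest["outputs"]["haplotype_catalog"] = "haplotype_catalog.tsv"

    # divergence -----------------------------------------------------------
    anc_seq = der_seq = None
    if not config.diagnostic_sites:
        anc_seq = apio.consensus_sequence([h.sequence for h in clade_I])
        der_seq = apio.consensus_sequence([h.sequence for h in clade_II])
    else:
        pure_anc = [
            p for p, h in zip(paintings, phased) if p.category == "ancestral"
        ]
        pure_der = [
            p for p, h in zip(paintings, phased) if p.category == "derived"
        ]
        if pure_anc and pure_der:
            anc_seq = apio.consensus_sequence(
                [h.sequence for h, p in zip(phased, paintings) if p.category == "ancestral"]
            )
            der_seq = apio.consensus_sequence(
                [h.sequence for h, p in zip(phased, paintings) if p.category == "derived"]
            )
    if anc_seq and der_seq:
        div = pairwise_divergence(
            anc_seq, der_seq, "clade_I_consensus", "clade_II_consensus",
            denominator=config.divergence_denominator,
        )
        stats = ng86_dnds(anc_seq, der_seq)
        div_df = pd.DataFrame(
            [
                {
                    "seq_a": div.seq_a_id,
                    "seq_b": div.seq_b_id,
                    "variant_sites": div.variant_sites,
                    "compared_sites": div.compared_sites,
                    "percent_divergence": round(div.percent, 2),
                    "denominator_mode": div.denominator_mode,
                    "N_sites": stats.N_sites,
                    "S_sites": stats.S_sites,
                    "Nd": stats.Nd,
                    "Sd": stats.Sd,
                    "dN": stats.dN,
                    "dS": stats.dS,
                    "omega": stats.omega,
                    "notes": stats.notes,
                }
            ]
        )
        _write_tsv(div_df, outdir / "divergence.tsv", params)
        manifest["clade_divergence_percent"] = round(div.percent, 2)
        manifest["outputs"]["divergence"] = "divergence.tsv"

    unique_seqs = sorted({h.sequence for h in phased})[:_MAX_SIMILARITY_SEQS]
    if len(unique_seqs) >= 2:
        sim, mean_ident = similarity_matrix(unique_seqs)
        sim.insert(0, "id", sim.index)
        _write_tsv(sim, outdir / "similarity_matrix.tsv", params)
        manifest["mean_identity_percent"] = round(mean_ident, 2)
        manifest["outputs"]["similarity_matrix"] = "similarity_matrix.tsv"
    manifest["stages"].append("divergence")

    # branch counts (optional) ---------------------------------------------
    if config.tree:
        recon = fitch_ancestral(
            config.tree,
            {h.name: h.sequence for h in phased},
            outgroup=config.outgroup or None,
        )
        counts = branch_substitutions(recon)
        screen = branch_omega_screen(counts)
        bdf = pd.DataFrame(
            {
                "branch": [b.branch for b in counts],
                "nonsynonymous": [b.nonsynonymous for b in counts],
                "synonymous": [b.synonymous for b in counts],
                "ambiguous": [b.ambiguous for b in counts],
                "p_fisher_vs_background": [r.p_value for r in screen],
                "elevated": [r.elevated for r in screen],
            }
        )
        _write_tsv(bdf, outdir / "branch_counts.tsv", params)
        manifest["stages"].append("branch_counts")
        manifest["fitch_parsimony_score"] = recon.score
        manifest["outputs"]["branch_counts"] = "branch_counts.tsv"

    # enrichment (optional) ------------------------------------------------
    if config.structure_pdb and config.poses:
        residues = load_residue_coordinates(config.structure_pdb)
        poses = load_poses(config.poses)
        segments = (
            read_tm_segments(config.tm_segments) if config.tm_segments else []
        )
        annotation = StructureAnnotation(
            residues=residues, poses=poses,
            tm_segments=segments, cutoff=config.cutoff,
        )
        protein_length = max(i for i, _ in residues)
        sub_residues = sorted({s.codon for s in sites if s.is_nonsynonymous})
        rows = []
        for mode in ("intersection", "union"):
            binding = ligand_binding_sites(annotation, mode=mode)
            res = enrichment_test(
                sub_residues, binding, protein_length,
                sidedness=config.sidedness, mode=mode,
            )
            rows.append(
                {
                    "mode": mode,
                    "n_binding": len(binding),
                    "a_sub_binding": res.table[0][0],
                    "b_sub_only": res.table[0][1],
                    "c_binding_only": res.table[1][0],
                    "d_neither": res.table[1][1],
                    "odds_ratio": res.odds_ratio,
                    "p_two_sided": res.p_two_sided,
                    "p_one_sided": res.p_one_sided,
                    "selected": mode == config.binding_mode,
                }
            )
            if mode == config.binding_mode:
                manifest["enrichment_p_value"] = res.p_value
                manifest["enrichment_odds_ratio"] = res.odds_ratio
        _write_tsv(pd.DataFrame(rows), outdir / "enrichment.tsv", params)
        if segments:
            seg_df = map_substitutions_to_segments(sub_residues, segments)
            _write_tsv(seg_df, outdir / "substitution_segments.tsv", params)
            manifest["outputs"]["substitution_segments"] = "substitution_segments.tsv"
        manifest["stages"].append("enrichment")
        manifest["outputs"]["enrichment"] = "enrichment.tsv"
    else:
        log.info("enrichment stage skipped: structure/pose inputs not configured")
        manifest["stages"].append("enrichment_skipped")

    return manifest
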