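"""Truth-labeled synthetic panels with the structure the analysis assumes.

The generator emulates a single-exon receptor CDS segregating as two
divergent allele clades: an intact ancestral CDS, a derived CDS differing
at a small number of planted diagnostic columns (with a controlled
synonymous/nonsynonymous split), lineages with clade frequencies under
Hardy-Weinberg pairing, crossover-derived mosaic haplotypes, and missing
data.  Defaults mirror the cichlid V1R2 study system: a 942-nt CDS
(314 codons) with 11 nonsynonymous diagnostic substitutions (pairwise
divergence 11/942 = 1.17%), Lake Tanganyika tribes fixed for one clade,
haplochromine lineages polymorphic, and riverine lineages carrying only
the ancestral clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .diagnostics import GENETIC_CODE, SENSE_CODONS
from .errors import ConfigError, DomainError, SimulationError
from .io import (
    write_genotypes_vcf,
    write_haplotype_fasta,
    write_metadata,
)
from .model import AlignedHaplotype, GenotypeRecord, SampleMetadata

_MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class LineageSpec:
    """One lineage: name, diploid sample count, derived-clade frequency."""

    name: str
    n_samples: int
    freq_derived: float


def default_lineages() -> list[LineageSpec]:
    # Figure-2-like mixture: lake tribes fixed or polymorphic, riverine ancestral-only
    return [
        LineageSpec("Lamprologini", 24, 1.0),
        LineageSpec("Ectodini", 24, 1.0),
        LineageSpec("Tropheini", 30, 0.65),
        LineageSpec("LakeMalawi", 60, 0.5),
        LineageSpec("LakeVictoria", 60, 0.5),
        LineageSpec("AfricanRiverine", 24, 0.0),
    ]


@dataclass
class SimulationConfig:
    n_codons: int = 314
    n_diagnostic: int = 11
    nonsyn_fraction: float = 1.0
    lineages: list[LineageSpec] = field(default_factory=default_lineages)
    recombinant_fraction: float = 0.0
    crossover_count_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_codons <= 0:
            raise ConfigError("n_codons must be positive")
        if not 0 <= self.n_diagnostic <= 3 * self.n_codons:
            raise ConfigError("n_diagnostic must be in [0, 3*n_codons]")
        for name, v in (
            ("nonsyn_fraction", self.nonsyn_fraction),
            ("recombinant_fraction", self.recombinant_fraction),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not self.lineages:
            raise ConfigError("at least one lineage is required")
        for lin in self.lineages:
            if lin.n_samples < 0 or not 0.0 <= lin.freq_derived <= 1.0:
                raise ConfigError(f"invalid lineage spec {lin}")
        if self.crossover_count_distribution:
            if any(
                k < 1 or p < 0 for k, p in self.crossover_count_distribution.items()
            ):
                raise ConfigError("crossover counts must be >=1 with p >= 0")
            if sum(self.crossover_count_distribution.values()) <= 0:
                raise ConfigError("crossover distribution has zero mass")

    # -- flat key=value round trip -------------------------------------
    def to_file(self, path: str | Path) -> None:
        lin = ";".join(
            f"{s.name}:{s.n_samples}:{s.freq_derived}" for s in self.lineages
        )
        xov = ";".join(
            f"{k}:{v}" for k, v in sorted(self.crossover_count_distribution.items())
        )
        lines = [
            f"n_codons={self.n_codons}",
            f"n_diagnostic={self.n_diagnostic}",
            f"nonsyn_fraction={self.nonsyn_fraction}",
            f"lineages={lin}",
            f"recombinant_fraction={self.recombinant_fraction}",
            f"crossover_count_distribution={xov}",
            f"missing_rate={self.missing_rate}",
            f"seed={self.seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
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
        try:
            if "n_codons" in kv:
                cfg.n_codons = int(kv["n_codons"])
            if "n_diagnostic" in kv:
                cfg.n_diagnostic = int(kv["n_diagnostic"])
            if "nonsyn_fraction" in kv:
                cfg.nonsyn_fraction = float(kv["nonsyn_fraction"])
            if "recombinant_fraction" in kv:
                cfg.recombinant_fraction = float(kv["recombinant_fraction"])
            if "missing_rate" in kv:
                cfg.missing_rate = float(kv["missing_rate"])
            if "seed" in kv:
                cfg.seed = int(kv["seed"])
            if "lineages" in kv:
                cfg.lineages = [
                    LineageSpec(n, int(c), float(f))
                    for n, c, f in (
                        part.split(":") for part in kv["lineages"].split(";") if part
                    )
                ]
            if "crossover_count_distribution" in kv:
                cfg.crossover_count_distribution = {
                    int(k): float(v)
                    for k, v in (
                        part.split(":")
                        for part in kv["crossover_count_distribution"].split(";")
                        if part
                    )
                }
        except ValueError as exc:
            raise ConfigError(f"cannot parse simulation config: {exc}") from exc
        cfg.validate()
        return cfg


@dataclass
class SimulationTruth:
    ancestral_cds: str
    derived_cds: str
    #: (column, ancestral base, derived base, is_nonsynonymous)
    diagnostic_columns: list[tuple[int, str, str, bool]]
    #: haplotype name -> ("cladeI" | "cladeII" | "recombinant", breakpoints)
    haplotype_labels: dict[str, tuple[str, list[int]]]
    #: sample_id -> genotype category
    sample_categories: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ancestral_cds": self.ancestral_cds,
            "derived_cds": self.derived_cds,
            "diagnostic_columns": [
                {"column": c, "ancestral": a, "derived": d, "nonsynonymous": ns}
                for c, a, d, ns in self.diagnostic_columns
            ],
            "haplotype_labels": {
                name: {"label": lab, "breakpoints": bps}
                for name, (lab, bps) in self.haplotype_labels.items()
            },
            "sample_categories": self.sample_categories,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            ancestral_cds=d["ancestral_cds"],
            derived_cds=d["derived_cds"],
            diagnostic_columns=[
                (x["column"], x["ancestral"], x["derived"], x["nonsynonymous"])
                for x in d["diagnostic_columns"]
            ],
            haplotype_labels={
                k: (v["label"], list(v["breakpoints"]))
                for k, v in d["haplotype_labels"].items()
            },
            sample_categories=dict(d["sample_categories"]),
        )


def _site_options(codon: str, pos: int) -> tuple[list[str], list[str]]:
    """Synonymous and nonsynonymous (non-stop) alternative bases at
    position ``pos`` of a sense codon."""
    syn, nonsyn = [], []
    aa = GENETIC_CODE[codon]
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        alt_aa = GENETIC_CODE[alt]
        if alt_aa == "*":
            continue
        (syn if alt_aa == aa else nonsyn).append(b)
    return syn, nonsyn


def simulate_divergent_alleles(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[str, str, list[tuple[int, str, str, bool]]]:
    """Generate an ancestral CDS and a derived CDS differing at exactly
    ``n_diagnostic`` columns, with the closest achievable nonsynonymous
    fraction and no premature stop codon in either allele."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    target = round(config.nonsyn_fraction * config.n_diagnostic)

    best: tuple[int, str, str, list[tuple[int, str, str, bool]]] | None = None
    for _ in range(_MAX_ATTEMPTS):
        codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), config.n_codons)]
        ancestral = "".join(codons)
        if config.n_diagnostic == 0:
            return ancestral, ancestral, []

        if config.n_diagnostic <= config.n_codons:
            # one planted site per codon: walk shuffled codons and take the
            # first whose options satisfy each requirement in turn
            requirements = ["nonsyn"] * target + ["syn"] * (
                config.n_diagnostic - target
            )
            rng.shuffle(requirements)
            pool = [int(x) for x in rng.permutation(config.n_codons)]
            plan: list[tuple[int, str, bool]] = []  # (column, base, nonsyn)
            ok = True
            for req in requirements:
                want = 1 if req == "nonsyn" else 0
                found = None
                for k, ci in enumerate(pool):
                    capable = [
                        (pos, _site_options(codons[ci], pos)[want])
                        for pos in range(3)
                    ]
                    capable = [(pos, opts) for pos, opts in capable if opts]
                    if capable:
                        found = k
                        pos, opts = capable[int(rng.integers(0, len(capable)))]
                        base = opts[int(rng.integers(0, len(opts)))]
                        plan.append((ci * 3 + pos + 1, base, want == 1))
                        break
                if found is None:
                    ok = False
                    break
                pool.pop(found)
            if not ok:
                continue
            plan.sort()
            realized = sum(ns for _, _, ns in plan)
            derived_list = list(ancestral)
            truth = []
            for col, base, ns in plan:
                truth.append((col, ancestral[col - 1], base, ns))
                derived_list[col - 1] = base
        else:
            # dense planting: several sites may share a codon
            columns = sorted(
                int(c) + 1
                for c in rng.choice(
                    3 * config.n_codons, config.n_diagnostic, replace=False
                )
            )
            options = {}
            feasible = True
            for col in columns:
                syn, nonsyn = _site_options(codons[(col - 1) // 3], (col - 1) % 3)
                if not syn and not nonsyn:
                    feasible = False
                    break
                options[col] = (syn, nonsyn)
            if not feasible:
                continue
            must_nonsyn = [c for c in columns if not options[c][0]]
            must_syn = [c for c in columns if not options[c][1]]
            lo, hi = len(must_nonsyn), config.n_diagnostic - len(must_syn)
            if lo > hi:
                continue
            realized = min(max(target, lo), hi)
            flexible = [c for c in columns if options[c][0] and options[c][1]]
            order = list(rng.permutation(len(flexible)))
            n_extra = realized - len(must_nonsyn)
            nonsyn_cols = set(must_nonsyn) | {flexible[i] for i in order[:n_extra]}
            derived_list = list(ancestral)
            truth = []
            for col in columns:
                syn, nonsyn = options[col]
                opts = nonsyn if col in nonsyn_cols else syn
                base = opts[int(rng.integers(0, len(opts)))]
                truth.append((col, ancestral[col - 1], base, col in nonsyn_cols))
                derived_list[col - 1] = base
        derived = "".join(derived_list)

        # joint stop check for shared-codon plantings
        if any(
            GENETIC_CODE[derived[i : i + 3]] == "*" for i in range(0, len(derived), 3)
        ):
            continue

        if realized == target:
            return ancestral, derived, truth
        if best is None or abs(realized - target) < abs(best[0] - target):
            best = (realized, ancestral, derived, truth)

    if best is None:
        raise SimulationError(
            f"could not plant {config.n_diagnostic} diagnostic sites with "
            f"nonsyn_fraction={config.nonsyn_fraction} in {_MAX_ATTEMPTS} attempts"
        )
    _, ancestral, derived, truth = best
    return ancestral, derived, truth


def simulate_recombinant(
    hapA: str, hapB: str, breakpoints: Sequence[int]
) -> str:
    """Mosaic of two aligned haplotypes: columns up to and including the
    first breakpoint copy ``hapA``, then the source alternates at each
    subsequent breakpoint."""
    if len(hapA) != len(hapB):
        raise ValueError("haplotypes differ in length")
    bps = list(breakpoints)
    if bps != sorted(set(bps)):
        raise ValueError("breakpoints must be strictly increasing")
    for b in bps:
        if not 1 <= b <= len(hapA):
            raise DomainError(f"breakpoint {b} outside sequence of length {len(hapA)}")
    out = []
    source = 0
    prev = 0
    for b in bps:
        out.append((hapA, hapB)[source][prev:b])
        source ^= 1
        prev = b
    out.append((hapA, hapB)[source][prev:])
    return "".join(out)


def _draw_crossover_count(
    dist: dict[int, float], rng: np.random.Generator
) -> int:
    ks = sorted(dist)
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    return int(rng.choice(ks, p=ps))


def simulate_panel(
    config: SimulationConfig,
) -> tuple[
    list[AlignedHaplotype],
    list[GenotypeRecord],
    list[SampleMetadata],
    SimulationTruth,
]:
    """Full diploid panel: per-lineage clade frequencies (Hardy-Weinberg
    pairing), optional crossover mosaics, optional missing data."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ancestral, derived, diag = simulate_divergent_alleles(config, rng)
    diag_cols = [c for c, _, _, _ in diag]

    haplotypes: list[AlignedHaplotype] = []
    metadata: list[SampleMetadata] = []
    hap_labels: dict[str, tuple[str, list[int]]] = {}
    sample_categories: dict[str, str] = {}

    for lin in config.lineages:
        for j in range(lin.n_samples):
            sample_id = f"{lin.name}-s{j + 1:03d}"
            metadata.append(
                SampleMetadata(sample_id, f"sp.{sample_id}", lin.name, "")
            )
            labels: list[str] = []
            for phase in (1, 2):
                is_derived = bool(rng.random() < lin.freq_derived)
                label = "cladeII" if is_derived else "cladeI"
                seq = derived if is_derived else ancestral
                breakpoints: list[int] = []
                if (
                    config.recombinant_fraction > 0
                    and len(diag_cols) >= 2
                    and rng.random() < config.recombinant_fraction
                ):
                    k = _draw_crossover_count(
                        config.crossover_count_distribution, rng
                    )
                    k = min(k, len(diag_cols) - 1)
                    gaps = sorted(
                        int(g)
                        for g in rng.choice(len(diag_cols) - 1, k, replace=False)
                    )
                    breakpoints = [
                        int(rng.integers(diag_cols[g], diag_cols[g + 1]))
                        for g in gaps
                    ]
                    other = ancestral if is_derived else derived
                    seq = simulate_recombinant(seq, other, breakpoints)
                    label = "recombinant"
                if config.missing_rate > 0:
                    mask = rng.random(len(seq)) < config.missing_rate
                    seq = "".join(
                        "N" if m else c for c, m in zip(seq, mask)
                    )
                hap = AlignedHaplotype(
                    sample_id, f"sp.{sample_id}", lin.name, phase, seq
                )
                haplotypes.append(hap)
                hap_labels[hap.name] = (label, breakpoints)
                labels.append(label)
            if "recombinant" in labels:
                sample_categories[sample_id] = "recombinant"
            elif labels == ["cladeI", "cladeI"]:
                sample_categories[sample_id] = "homozygote_I"
            elif labels == ["cladeII", "cladeII"]:
                sample_categories[sample_id] = "homozygote_II"
            else:
                sample_categories[sample_id] = "heterozygote"

    by_sample: dict[str, list[AlignedHaplotype]] = {}
    for h in haplotypes:
        by_sample.setdefault(h.sample_id, []).append(h)
    genotypes = [
        GenotypeRecord(
            sample_id=s,
            site=col,
            alleles=(pair[0].sequence[col - 1], pair[1].sequence[col - 1]),
            phased=True,
        )
        for s, pair in by_sample.items()
        for col in diag_cols
    ]

    truth = SimulationTruth(
        ancestral_cds=ancestral,
        derived_cds=derived,
        diagnostic_columns=diag,
        haplotype_labels=hap_labels,
        sample_categories=sample_categories,
    )
    return haplotypes, genotypes, metadata, truth


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a panel and write the full input bundle the pipeline
    consumes: FASTA, VCF, metadata TSV, clade reference lists, truth
    tables, and the config used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    haplotypes, genotypes, metadata, truth = simulate_panel(config)

    paths = {
        "fasta": outdir / "haplotypes.fasta",
        "vcf": outdir / "genotypes.vcf",
        "metadata": outdir / "metadata.tsv",
        "truth_json": outdir / "truth.json",
        "truth_haplotypes": outdir / "truth_haplotypes.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
        "clade_I_refs": outdir / "clade_I_refs.txt",
        "clade_II_refs": outdir / "clade_II_refs.txt",
        "reference": outdir / "ancestral_reference.fasta",
        "config": outdir / "sim_config.txt",
    }
    write_haplotype_fasta(haplotypes, paths["fasta"])
    write_genotypes_vcf(genotypes, truth.ancestral_cds, paths["vcf"])
    write_metadata(metadata, paths["metadata"])
    truth.to_json(paths["truth_json"])

    with open(paths["truth_haplotypes"], "w") as fh:
        fh.write("haplotype\tlabel\tbreakpoints\n")
        for name, (label, bps) in truth.haplotype_labels.items():
            fh.write(f"{name}\t{label}\t{','.join(map(str, bps))}\n")
    with open(paths["truth_samples"], "w") as fh:
        fh.write("sample_id\tcategory\n")
        for s, cat in truth.sample_categories.items():
            fh.write(f"{s}\t{cat}\n")

    clade_I = [n for n, (lab, _) in truth.haplotype_labels.items() if lab == "cladeI"]
    clade_II = [n for n, (lab, _) in truth.haplotype_labels.items() if lab == "cladeII"]
    if not clade_I or not clade_II:
        raise SimulationError(
            "panel lacks pure haplotypes of one clade; cannot write reference lists"
        )
    paths["clade_I_refs"].write_text("\n".join(clade_I) + "\n")
    paths["clade_II_refs"].write_text("\n".join(clade_II) + "\n")
    paths["reference"].write_text(f">reference\n{truth.ancestral_cds}\n")
    config.to_file(paths["config"])
    return paths
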