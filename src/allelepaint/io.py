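"""Readers and writers for the external formats.

FASTA (one record per haplotype, header ``sampleID_1``/``sampleID_2`` for
phased copies or plain ``sampleID`` for an unphased IUPAC sequence), a
minimal VCF v4.2 subset (CHROM/POS/REF/ALT/GT, biallelic-after-splitting
SNPs only), and a metadata TSV with columns sample_id/species/lineage/lake.
FASTA goes through Bio.SeqIO and VCF through pysam.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, FormatError, UnsupportedRecordError
from .model import (
    AlignedHaplotype,
    GenotypeRecord,
    SampleMetadata,
    validate_alignment,
)

log = logging.getLogger(__name__)

# unordered base pair -> IUPAC code (plus degenerate pairs)
_IUPAC_COLLAPSE = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
_IUPAC_EXPAND = {code: pair for pair, code in _IUPAC_COLLAPSE.items()}
_IUPAC_EXPAND["N"] = frozenset("N")
_IUPAC_EXPAND["-"] = frozenset("-")

VALID_HAPLOTYPE_CHARS = frozenset("ACGTN-")


def iupac_collapse(hap1: str, hap2: str) -> str:
    """Collapse two phased sequences into one unphased IUPAC sequence."""
    if len(hap1) != len(hap2):
        raise AlignmentError("phased sequences differ in length")
    out = []
    for a, b in zip(hap1.upper(), hap2.upper()):
        if a not in VALID_HAPLOTYPE_CHARS or b not in VALID_HAPLOTYPE_CHARS:
            raise FormatError(f"non-IUPAC character in pair ({a}, {b})")
        if a == "-" and b == "-":
            out.append("-")
        elif a in "N-" or b in "N-":
            out.append("N")
        else:
            out.append(_IUPAC_COLLAPSE[frozenset((a, b))])
    return "".join(out)


def iupac_expand(seq: str) -> list[frozenset[str]]:
    """Per-site unordered allele pairs of an unphased IUPAC sequence.

    Each element is a frozenset of one base (homozygous) or two bases
    (heterozygous); ``N``/``-`` expand to themselves.
    """
    pairs = []
    for c in seq.upper():
        if c not in _IUPAC_EXPAND:
            raise FormatError(f"non-IUPAC character {c!r}")
        pairs.append(_IUPAC_EXPAND[c])
    return pairs


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"sample_id", "species", "lineage"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata TSV missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id in metadata: {dups}")
    if "lake" not in df.columns:
        df["lake"] = ""
    return {
        r.sample_id: SampleMetadata(r.sample_id, r.species, r.lineage, r.lake)
        for r in df.itertuples()
    }


def write_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = [
        (m.sample_id, m.species, m.lineage, m.lake) for m in records
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "species", "lineage", "lake"]
    ).to_csv(path, sep="\t", index=False)


def _parse_header(header: str) -> tuple[str, int | str]:
    """Split a FASTA id into (sample_id, phase)."""
    for suffix, phase in (("_1", 1), ("_2", 2)):
        if header.endswith(suffix):
            return header[: -len(suffix)], phase
    return header, "unphased"


def read_haplotype_fasta(
    path: str | Path,
    metadata_path: str | Path,
    trailing_bases: int = 0,
) -> list[AlignedHaplotype]:
    """Read an aligned haplotype FASTA joined to its metadata table.

    Raises ``AlignmentError`` on ragged input or bad codon frame,
    ``FormatError`` on duplicate (sample, phase) pairs or haplotypes
    whose sample is absent from the metadata.
    """
    metadata = read_metadata(metadata_path)
    haplotypes: list[AlignedHaplotype] = []
    seen: set[tuple[str, int | str]] = set()
    unmatched: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        sample_id, phase = _parse_header(record.id)
        key = (sample_id, phase)
        if key in seen:
            raise FormatError(f"duplicate haplotype for {sample_id!r} phase {phase}")
        seen.add(key)
        meta = metadata.get(sample_id)
        if meta is None:
            unmatched.append(sample_id)
            continue
        haplotypes.append(
            AlignedHaplotype(
                sample_id=sample_id,
                species=meta.species,
                lineage=meta.lineage,
                phase=phase,
                sequence=str(record.seq).upper(),
            )
        )
    if unmatched:
        raise FormatError(
            f"{len(unmatched)} haplotype(s) without metadata: {sorted(set(unmatched))}"
        )
    if not haplotypes:
        raise FormatError(f"no FASTA records in {path}")
    validate_alignment(haplotypes, trailing_bases=trailing_bases)
    extra = set(metadata) - {h.sample_id for h in haplotypes}
    if extra:
        log.warning("%d metadata rows without haplotypes: %s", len(extra), sorted(extra))
    return haplotypes


def write_haplotype_fasta(
    haplotypes: Sequence[AlignedHaplotype], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(h.sequence), id=h.name, description="") for h in haplotypes
    ]
    SeqIO.write(records, str(path), "fasta")


def _check_snp_record(rec) -> None:
    if len(rec.ref) != 1:
        raise UnsupportedRecordError(
            f"record at POS {rec.pos}: REF {rec.ref!r} is not a single base"
        )
    for alt in rec.alts or ():
        if alt in ("*", "<NON_REF>") or len(alt) != 1:
            raise UnsupportedRecordError(
                f"record at POS {rec.pos}: ALT {alt!r} unsupported "
                "(only biallelic-after-splitting SNPs are accepted)"
            )


def read_genotypes_vcf(vcf_path: str | Path, n_columns: int) -> list[GenotypeRecord]:
    """Read per-sample diploid genotypes from a VCF subset.

    Multi-allelic SNP records are handled by direct allele-index lookup
    (equivalent to splitting). Indels and other non-SNP records raise.
    """
    records: list[GenotypeRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            _check_snp_record(rec)
            if rec.pos < 1 or rec.pos > n_columns:
                raise FormatError(
                    f"POS {rec.pos} outside alignment of length {n_columns}"
                )
            alleles = (rec.ref,) + tuple(rec.alts or ())
            for sample, call in rec.samples.items():
                gt = call["GT"]
                if gt is None or len(gt) != 2:
                    raise UnsupportedRecordError(
                        f"sample {sample} at POS {rec.pos}: ploidy != 2"
                    )
                pair = tuple(
                    "N" if idx is None else alleles[idx].upper() for idx in gt
                )
                records.append(
                    GenotypeRecord(
                        sample_id=sample,
                        site=rec.pos,
                        alleles=pair,  # type: ignore[arg-type]
                        phased=bool(call.phased),
                    )
                )
    return records


def read_vcf_to_haplotypes(
    vcf_path: str | Path,
    reference_seq: str,
    metadata_path: str | Path,
    trailing_bases: int = 0,
) -> list[AlignedHaplotype]:
    """Build aligned haplotypes by applying VCF genotypes to a reference.

    Samples whose heterozygous genotypes are all phased yield two
    haplotypes (phase 1 and 2); a sample with any unphased heterozygote
    yields a single "unphased" IUPAC-coded haplotype.
    """
    metadata = read_metadata(metadata_path)
    reference_seq = reference_seq.upper()
    with pysam.VariantFile(str(vcf_path)) as vcf:
        header_samples = list(vcf.header.samples)
    genotypes = read_genotypes_vcf(vcf_path, n_columns=len(reference_seq))

    # samples with no variant records get plain reference haplotypes
    by_sample: dict[str, list[GenotypeRecord]] = {s: [] for s in header_samples}
    for g in genotypes:
        by_sample.setdefault(g.sample_id, []).append(g)

    haplotypes: list[AlignedHaplotype] = []
    for sample_id, recs in by_sample.items():
        meta = metadata.get(sample_id)
        if meta is None:
            raise FormatError(f"VCF sample {sample_id!r} absent from metadata")
        fully_phased = all(g.phased or g.alleles[0] == g.alleles[1] for g in recs)
        h1 = list(reference_seq)
        h2 = list(reference_seq)
        for g in recs:
            h1[g.site - 1], h2[g.site - 1] = g.alleles
        if fully_phased:
            for phase, seq in ((1, h1), (2, h2)):
                haplotypes.append(
                    AlignedHaplotype(
                        sample_id, meta.species, meta.lineage, phase, "".join(seq)
                    )
                )
        else:
            haplotypes.append(
                AlignedHaplotype(
                    sample_id,
                    meta.species,
                    meta.lineage,
                    "unphased",
                    iupac_collapse("".join(h1), "".join(h2)),
                )
            )
    validate_alignment(haplotypes, trailing_bases=trailing_bases)
    return haplotypes


def write_genotypes_vcf(
    genotypes: Sequence[GenotypeRecord],
    reference_seq: str,
    path: str | Path,
    contig: str = "gene",
) -> None:
    """Write diploid genotypes at variant columns as an uncompressed VCF."""
    by_site: dict[int, dict[str, GenotypeRecord]] = {}
    samples: list[str] = []
    for g in genotypes:
        by_site.setdefault(g.site, {})[g.sample_id] = g
        if g.sample_id not in samples:
            samples.append(g.sample_id)

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={len(reference_seq)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(by_site):
            ref = reference_seq[site - 1]
            alts: list[str] = []
            for g in by_site[site].values():
                for a in g.alleles:
                    if a not in ("N", ref) and a not in alts:
                        alts.append(a)
            if not alts:
                continue
            alleles = (ref,) + tuple(sorted(alts))
            rec = out.new_record(
                contig=contig, start=site - 1, stop=site, alleles=alleles
            )
            for s in samples:
                g = by_site[site].get(s)
                if g is None:
                    rec.samples[s]["GT"] = (0, 0)
                    rec.samples[s].phased = True
                    continue
                idx = tuple(
                    None if a == "N" else alleles.index(a) for a in g.alleles
                )
                rec.samples[s]["GT"] = idx
                rec.samples[s].phased = g.phased
            out.write(rec)


def consensus_sequence(sequences: Sequence[str]) -> str:
    """Column-wise majority consensus ignoring missing; ties alphabetical."""
    if not sequences:
        raise FormatError("no sequences for consensus")
    length = len(sequences[0])
    out = []
    for i in range(length):
        counts: dict[str, int] = {}
        for s in sequences:
            c = s[i]
            if c not in "N-":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("N")
        else:
            out.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(out)


def partition_by_names(
    haplotypes: Sequence[AlignedHaplotype], names: Iterable[str]
) -> list[AlignedHaplotype]:
    """Select haplotypes by their FASTA-style names (``sample_phase``)."""
    wanted = set(names)
    selected = [h for h in haplotypes if h.name in wanted]
    missing = wanted - {h.name for h in selected}
    if missing:
        raise FormatError(f"reference haplotypes not found: {sorted(missing)}")
    return selected
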