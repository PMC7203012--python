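"""Readers/writers for the package's external formats.

FASTA alignment record ids are ``taxon|subgenome|gene`` (subgenome ``O``
for taxa without one); tracks are bedGraph-dialect TSV (0-based half-open);
VCF is v4.2 with phased GT.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .gene_flux import PresenceMatrix
from .recomb_epigenome import GenotypePanel
from .synthetic_data.history import SpeciesHistory
from .synthetic_data.ltr import LTRPair, LTRPairSet
from .synthetic_data.sequences import AlignmentSet, GeneTruth, SimTruth

__all__ = [
    "tip_to_record_id",
    "record_id_to_tip",
    "write_alignments",
    "read_alignments",
    "write_history",
    "read_history",
    "write_ltr_fasta",
    "read_ltr_fasta",
    "write_vcf",
    "read_vcf",
    "write_track",
    "read_track",
    "write_table",
    "read_table",
    "write_presence",
    "read_presence",
    "write_truth",
    "read_truth",
]


def tip_to_record_id(tip: str, gene: str) -> str:
    if tip.endswith(("_A", "_D")):
        taxon, sub = tip.rsplit("_", 1)
    elif tip == "Ga":
        taxon, sub = tip, "A"
    elif tip == "Gr":
        taxon, sub = tip, "D"
    else:
        taxon, sub = tip, "O"
    return f"{taxon}|{sub}|{gene}"


def record_id_to_tip(record_id: str) -> tuple[str, str]:
    """Returns (tip name, gene)."""
    taxon, sub, gene = record_id.split("|", 2)
    if sub in ("A", "D") and taxon not in ("Ga", "Gr"):
        return f"{taxon}_{sub}", gene
    return taxon, gene


def write_alignments(aln: AlignmentSet, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for gene in aln:
        records = [
            SeqRecord(Seq(seq), id=tip_to_record_id(tip, gene), description="")
            for tip, seq in aln[gene].items()
        ]
        path = directory / f"{gene}.fasta"
        SeqIO.write(records, path, "fasta")
        paths.append(path)
    return paths


def read_alignments(directory: str | Path) -> AlignmentSet:
    aln = AlignmentSet()
    for path in sorted(Path(directory).glob("*.fasta")):
        seqs = {}
        gene = path.stem
        for rec in SeqIO.parse(path, "fasta"):
            tip, gene = record_id_to_tip(rec.id)
            seqs[tip] = str(rec.seq)
        aln.genes[gene] = seqs
    return aln


def write_history(history: SpeciesHistory, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(history.to_newick() + "\n")
    return path


def read_history(path: str | Path) -> SpeciesHistory:
    return SpeciesHistory.from_newick(Path(path).read_text())


def write_ltr_fasta(pairs: LTRPairSet, path: str | Path) -> Path:
    path = Path(path)
    records = []
    for pair in pairs:
        records.append(SeqRecord(Seq(pair.five_prime), id=f"{pair.element_id}|5ltr", description=""))
        records.append(SeqRecord(Seq(pair.three_prime), id=f"{pair.element_id}|3ltr", description=""))
    SeqIO.write(records, path, "fasta")
    return path


def read_ltr_fasta(path: str | Path) -> LTRPairSet:
    five: dict[str, str] = {}
    three: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        elem, side = rec.id.rsplit("|", 1)
        (five if side == "5ltr" else three)[elem] = str(rec.seq)
    if set(five) != set(three):
        raise ValueError("unpaired LTR records in FASTA")
    return LTRPairSet([LTRPair(e, five[e], three[e]) for e in sorted(five)])


def write_vcf(panel: GenotypePanel, path: str | Path) -> Path:
    path = Path(path)
    n_samples = panel.n_haplotypes // 2
    samples = [f"S{i:04d}" for i in range(n_samples)]
    max_pos = int(panel.positions.max()) if panel.n_snps else 1
    lines = [
        "##fileformat=VCFv4.2",
        "##source=polyrate",
        f"##contig=<ID={panel.chrom},length={max_pos + 1}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for j in range(panel.n_snps):
        gts = []
        for s in range(n_samples):
            a, b = panel.haplotypes[2 * s, j], panel.haplotypes[2 * s + 1, j]
            gts.append(f"{'.' if a < 0 else a}|{'.' if b < 0 else b}")
        lines.append(
            f"{panel.chrom}\t{panel.positions[j]}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path) -> GenotypePanel:
    vcf = VCF(str(path))
    positions = []
    haps = []
    chrom = None
    for variant in vcf:
        chrom = variant.CHROM
        positions.append(variant.POS)
        row = []
        for g in variant.genotypes:
            a, b = g[0], g[1]
            row.extend([a if a >= 0 else -1, b if b >= 0 else -1])
        haps.append(row)
    vcf.close()
    if not positions:
        raise ValueError(f"no variants in {path}")
    return GenotypePanel(chrom, np.array(positions), np.array(haps, dtype=np.int8).T)


def write_track(track: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    track[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)
    return path


def read_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"])


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_presence(matrix: PresenceMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "group"
    df.to_csv(path, sep="\t")
    return path


def read_presence(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="group")
    return PresenceMatrix(list(map(str, df.index)), list(df.columns), df.to_numpy())


def write_truth(truth: SimTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "genes": {g: asdict(t) for g, t in truth.genes.items()},
        "presence_events": truth.presence_events,
        "ltr_ages": truth.ltr_ages,
        "blocks": [list(b) for b in truth.blocks],
        "effects": truth.effects,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    truth = SimTruth()
    truth.genes = {g: GeneTruth(**t) for g, t in payload.get("genes", {}).items()}
    truth.presence_events = payload.get("presence_events", [])
    truth.ltr_ages = payload.get("ltr_ages", {})
    truth.blocks = [tuple(b) for b in payload.get("blocks", [])]
    truth.effects = payload.get("effects", {})
    return truth
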