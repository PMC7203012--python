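"""k-mer spectrum comparison and TE-cluster sharedness classification."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "KmerSpectrum",
    "TECluster",
    "TEClusterSet",
    "kmer_spectrum",
    "cumulative_curve",
    "cluster_te_sequences",
    "classify_cluster_sharing",
]


@dataclass(frozen=True)
class KmerSpectrum:
    k: int
    #: frequency class -> number of distinct k-mers occurring that many times
    counts: dict[int, int]

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())

    @property
    def total_occurrences(self) -> int:
        return sum(freq * n for freq, n in self.counts.items())


@dataclass
class TECluster:
    cluster_id: int
    representative: str
    members: list[str] = field(default_factory=list)
    genomes: list[str] = field(default_factory=list)


@dataclass
class TEClusterSet:
    clusters: list[TECluster]
    identity_threshold: float


def kmer_spectrum(
    sequences, k: int, canonical: bool = False
) -> KmerSpectrum:
    """Exact k-mer frequency spectrum over a sequence collection.

    k-mers containing N are skipped.  With ``canonical=True`` each k-mer is
    pooled with its reverse complement (lexicographically smaller form
    kept); the default counts the given strand only.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(sequences, str):
        sequences = [sequences]
    seqs = [str(s).upper() for s in sequences]
    if seqs and all(len(s) < k for s in seqs):
        raise ValueError(f"k = {k} is longer than every input sequence")
    counts: Counter[str] = Counter()
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            if canonical:
                rc = str(Seq(kmer).reverse_complement())
                kmer = min(kmer, rc)
            counts[kmer] += 1
    spectrum = Counter(counts.values())
    return KmerSpectrum(k, dict(sorted(spectrum.items())))


def cumulative_curve(spectra: dict[str, KmerSpectrum]) -> pd.DataFrame:
    """Per label, cumulative % of distinct k-mers at frequency <= x.

    Columns: label, frequency, cumulative_pct.  Monotone non-decreasing per
    label, ending at 100%.
    """
    ks = {s.k for s in spectra.values()}
    if len(ks) > 1:
        raise ValueError(f"mixed k across spectra: {sorted(ks)}")
    rows = []
    for label, spec in spectra.items():
        total = spec.total_distinct
        running = 0
        for freq in sorted(spec.counts):
            running += spec.counts[freq]
            rows.append((label, freq, 100.0 * running / total))
    return pd.DataFrame(rows, columns=["label", "frequency", "cumulative_pct"])


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)


def _global_identity(a: str, b: str) -> float:
    """Matches over alignment columns of a global pairwise alignment."""
    alignment = _ALIGNER.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return matches / len(sa)


def cluster_te_sequences(
    tes: dict[str, tuple[str, str]], threshold: float = 0.90
) -> TEClusterSet:
    """Greedy longest-first clustering at > *threshold* global identity.

    *tes* maps member id -> (sequence, source-genome label).  Members are
    taken longest first (ties by id) and join the first existing cluster
    whose representative they match at > threshold identity, otherwise
    found a new cluster.  This ordering makes the result independent of the
    input order.
    """
    if not tes:
        raise ValueError("empty input")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for mid, (seq, _genome) in tes.items():
        if len(seq) < 100:
            raise ValueError(f"sequence {mid!r} is shorter than 100 bp")
    order = sorted(tes, key=lambda m: (-len(tes[m][0]), m))
    clusters: list[TECluster] = []
    for mid in order:
        seq, genome = tes[mid]
        placed = False
        for cl in clusters:
            if _global_identity(seq, cl.representative) > threshold:
                cl.members.append(mid)
                cl.genomes.append(genome)
                placed = True
                break
        if not placed:
            clusters.append(TECluster(len(clusters), seq, [mid], [genome]))
    return TEClusterSet(clusters, threshold)


def classify_cluster_sharing(cluster_set: TEClusterSet) -> pd.DataFrame:
    """Per cluster: specific (one source genome) vs shared, plus per-genome
    summary counts in ``DataFrame.attrs['per_genome']``."""
    rows = []
    per_genome: Counter[str] = Counter()
    for cl in cluster_set.clusters:
        if any(g is None or g == "" for g in cl.genomes):
            raise ValueError(f"cluster {cl.cluster_id} has unlabeled members")
        genomes = sorted(set(cl.genomes))
        status = "specific" if len(genomes) == 1 else "shared"
        for g in genomes:
            per_genome[(g, status)] += 1
        rows.append((cl.cluster_id, len(cl.members), status, ",".join(genomes)))
    df = pd.DataFrame(rows, columns=["cluster_id", "n_members", "status", "genomes"])
    df.attrs["per_genome"] = {
        g: {
            "specific": per_genome.get((g, "specific"), 0),
            "shared": per_genome.get((g, "shared"), 0),
        }
        for g in sorted({g for g, _ in per_genome})
    }
    return df
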