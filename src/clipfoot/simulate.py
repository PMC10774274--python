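"""Synthetic data with the statistical structure the footprint analysis assumes.

Everything the pipeline consumes can be generated here: a toy genome
annotation, true binding sites biased toward introns, per-replicate scored
peak sets drawn from a two-component (reproducible / irreproducible) score
model, background contamination, footprint sequences with planted motifs,
and junction-count / Ct / band-intensity assay tables.

Every generator is a pure function of ``(scenario, seed)``: the same
scenario produces byte-identical outputs.  Per-stage substreams are derived
from the root seed so stages can be re-run in isolation.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GenomeAnnotation,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    REGION_CLASSES,
)

__all__ = [
    "SyntheticScenario",
    "make_toy_annotation",
    "simulate_true_sites",
    "simulate_replicate_peaks",
    "simulate_background",
    "simulate_sequences",
    "simulate_assay_tables",
]

# stage tags for substream derivation
_STAGE = {
    "annotation": 11,
    "sites": 23,
    "peaks": 37,
    "background": 41,
    "sequences": 53,
    "assays": 67,
}


def _rng(seed: int, stage: str, *extra: str | int) -> np.random.Generator:
    """Substream generator: root seed + stage tag + stable extras."""
    keys = [int(seed), _STAGE[stage]]
    for x in extra:
        if isinstance(x, str):
            keys.append(zlib.crc32(x.encode()) & 0x7FFFFFFF)
        else:
            keys.append(int(x) & 0x7FFFFFFF)
    return np.random.default_rng(keys)


@dataclass
class SyntheticScenario:
    """Full generative configuration for a reproducible simulation.

    The score model mirrors a two-component Gaussian copula mixture: a
    fraction ``reproducible_fraction`` of matched peaks draw correlated
    latent scores from N(signal_mean, signal_sd^2) with pairwise correlation
    ``signal_corr``; the rest draw independent standard-normal latents.
    Latents are emitted both as positive real scores (exp(latent)) and as
    integer read-support counts (Poisson with mean exp(latent))), so
    pseudo-replicate binomial thinning is well defined.

    ``condition_loss`` maps condition labels to the fraction of true sites
    removed in that condition; the defaults encode a naive / mild / severe
    disease series in which severe samples lose half of the binding sites.
    """

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 60
    # true sites
    n_true_sites: int = 300
    region_bias: dict[str, float] = field(default_factory=lambda: {
        "intron": 0.6, "CDS": 0.2, "three_prime_utr": 0.1,
        "five_prime_utr": 0.1})
    site_width_min: int = 20
    site_width_max: int = 60
    # replicate score model
    reproducible_fraction: float = 0.65
    signal_mean: float = 2.5
    signal_sd: float = 1.0
    signal_corr: float = 0.8
    n_noise_peaks_per_rep: int = 100
    # background + conditions
    background_rate: float = 0.05          # peaks per kb
    condition_loss: dict[str, float] = field(default_factory=lambda: {
        "naive": 0.0, "mild": 0.25, "severe": 0.5})
    # motif model
    motif: str = "UAG"
    motif_enrichment: float = 5.0
    # assay tables
    junction_depth: int = 2000
    psi_by_group: dict[str, float] = field(default_factory=lambda: {
        "control": 0.7, "case": 0.4})
    n_samples_per_group: int = 5
    inclusion_len: int = 150
    skipping_len: int = 100
    ct_reference: float = 20.0
    ct_shift_by_group: dict[str, float] = field(default_factory=lambda: {
        "control": 0.0, "case": 1.0})
    ct_noise_sd: float = 0.05
    band_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.n_true_sites > 0:
            if not 0.0 <= self.reproducible_fraction <= 1.0:
                raise ValueError("reproducible_fraction must be in [0,1]")
        if not 0.0 <= self.signal_corr < 1.0:
            raise ValueError("signal_corr must be in [0,1)")
        if self.signal_sd <= 0 or self.signal_mean <= 0:
            raise ValueError("signal_mean and signal_sd must be positive")
        if abs(sum(self.region_bias.values()) - 1.0) > 1e-9:
            raise ValueError("region_bias must sum to 1")
        for cls in self.region_bias:
            if cls not in REGION_CLASSES:
                raise ValueError(f"unknown region class {cls!r}")
        for label, frac in self.condition_loss.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"condition_loss[{label!r}] outside [0,1]")
        for g, p in self.psi_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"psi_by_group[{g!r}] outside [0,1]")
        for n in (self.n_chroms, self.chrom_length, self.n_genes,
                  self.n_true_sites, self.n_noise_peaks_per_rep):
            if n < 0:
                raise ValueError("counts must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if self.motif_enrichment < 1.0:
            raise ValueError("motif_enrichment must be >= 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=True)
                if path.suffix in (".yml", ".yaml")
                else json.dumps(self.to_dict(), indent=2, sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticScenario":
        path = Path(path)
        text = path.read_text()
        d = (yaml.safe_load(text) if path.suffix in (".yml", ".yaml")
             else json.loads(text))
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def make_toy_annotation(scenario: SyntheticScenario) -> GenomeAnnotation:
    """Place non-overlapping toy gene models on the toy chromosomes.

    Each gene is a single transcript laid out contiguously: a 5'UTR, two to
    four CDS exons separated by introns, and a 3'UTR (order reversed on the
    minus strand).  Intergenic gaps separate genes.  Raises if the requested
    genes cannot be placed without overlap.
    """
    rng = _rng(scenario.seed, "annotation")
    chroms = [f"chr{i + 1}" for i in range(scenario.n_chroms)]
    chrom_sizes = {c: scenario.chrom_length for c in chroms}
    if scenario.n_genes == 0:
        return GenomeAnnotation([], chrom_sizes)

    genes: list[GeneModel] = []
    per_chrom = np.array_split(np.arange(scenario.n_genes), scenario.n_chroms)
    for chrom, idxs in zip(chroms, per_chrom):
        n_here = len(idxs)
        if n_here == 0:
            continue
        # draw structures first so total length is known before placement
        structures = []
        for gi in idxs:
            n_cds = int(rng.integers(2, 5))
            utr5 = int(rng.integers(100, 301))
            utr3 = int(rng.integers(150, 401))
            cds = [int(rng.integers(80, 301)) for _ in range(n_cds)]
            introns = [int(rng.integers(500, 2001)) for _ in range(n_cds - 1)]
            strand = "+" if rng.random() < 0.5 else "-"
            structures.append((int(gi), strand, utr5, cds, introns, utr3))
        total = sum(s[2] + sum(s[3]) + sum(s[4]) + s[5] for s in structures)
        slack = scenario.chrom_length - total
        if slack < n_here + 1:
            raise ValueError(
                f"cannot place {n_here} genes on {chrom}: need {total} nt "
                f"plus gaps, have {scenario.chrom_length}")
        # dirichlet-ish gaps: random split of the slack into n+1 gaps, each >=1
        cuts = np.sort(rng.choice(slack - (n_here + 1), size=n_here, replace=False))
        gaps = np.diff(np.concatenate([[0], cuts, [slack - (n_here + 1)]])) + 1
        pos = 0
        for (gi, strand, utr5, cds, introns, utr3), gap in zip(structures, gaps):
            pos += int(gap)
            start = pos
            # genomic left-to-right order of the transcript blocks
            blocks = [("five_prime_utr", utr5)]
            for j, clen in enumerate(cds):
                blocks.append(("CDS", clen))
                if j < len(introns):
                    blocks.append(("intron", introns[j]))
            blocks.append(("three_prime_utr", utr3))
            if strand == "-":
                blocks = blocks[::-1]
            regions: dict[str, list[tuple[int, int]]] = {}
            p = start
            for cls, length in blocks:
                regions.setdefault(cls, []).append((p, p + length))
                p += length
            genes.append(GeneModel(
                gene_id=f"gene{gi + 1:04d}", chrom=chrom, strand=strand,
                start=start, end=p, regions=regions))
            pos = p
    return GenomeAnnotation(genes, chrom_sizes)


# ---------------------------------------------------------------------------
# true sites / peaks / background
# ---------------------------------------------------------------------------

def simulate_true_sites(annotation: GenomeAnnotation,
                        scenario: SyntheticScenario) -> IntervalSet:
    """True binding sites, each fully inside a sampled genic region class.

    Region classes are drawn from ``region_bias`` (intron-heavy by default)
    and a span of that class wide enough to hold the site is chosen with
    probability proportional to the number of valid placements.
    """
    rng = _rng(scenario.seed, "sites")
    if scenario.n_true_sites == 0:
        return IntervalSet([], sample_id="true_sites")

    classes = sorted(scenario.region_bias)
    probs = np.array([scenario.region_bias[c] for c in classes])
    spans_by_class: dict[str, list[GenomicInterval]] = {
        c: list(annotation.region_intervals(c)) for c in classes}

    sites: list[GenomicInterval] = []
    for i in range(scenario.n_true_sites):
        width = int(rng.integers(scenario.site_width_min,
                                 scenario.site_width_max + 1))
        placed = False
        for _ in range(50):  # bounded retries over class draws
            cls = classes[int(rng.choice(len(classes), p=probs))]
            spans = [s for s in spans_by_class[cls] if len(s) >= width]
            if not spans:
                continue
            w = np.array([len(s) - width + 1 for s in spans], dtype=float)
            span = spans[int(rng.choice(len(spans), p=w / w.sum()))]
            off = int(rng.integers(0, len(span) - width + 1))
            sites.append(GenomicInterval(
                span.chrom, span.start + off, span.start + off + width,
                span.strand, name=f"site{i + 1:05d}"))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place site of width {width}: regions too small")
    return IntervalSet(sites, sample_id="true_sites").sorted()


def replace_name(iv: GenomicInterval, name: str) -> GenomicInterval:
    from dataclasses import replace
    return replace(iv, name=name)


def _emit_peak(iv: GenomicInterval, latent: float,
               rng: np.random.Generator) -> GenomicInterval:
    from dataclasses import replace
    score = float(np.exp(latent))
    count = int(rng.poisson(score))
    return replace(iv, score=score, count=count)


def simulate_replicate_peaks(
    true_sites: IntervalSet,
    scenario: SyntheticScenario,
    n_reps: int,
    condition: str = "naive",
) -> list[IntervalSet]:
    """Per-replicate scored peak sets for one condition.

    A fraction ``condition_loss[condition]`` of true sites is removed for the
    whole condition.  Each retained site is reproducible with probability
    ``reproducible_fraction``: all replicates then receive a peak there with
    latent scores drawn jointly from the equicorrelated signal component
    (mean ``signal_mean``, sd ``signal_sd``, pairwise corr ``signal_corr``);
    otherwise each replicate draws an independent standard-normal latent.
    Each replicate also receives ``n_noise_peaks_per_rep`` unmatched noise
    peaks.  Scores are exp(latent); integer counts are Poisson(exp(latent)).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    loss = scenario.condition_loss.get(condition, 0.0)
    rng = _rng(scenario.seed, "peaks", condition)

    n_sites = len(true_sites)
    n_keep = n_sites - int(round(loss * n_sites))
    keep_idx = np.sort(rng.choice(n_sites, size=n_keep, replace=False)) \
        if n_sites else np.array([], dtype=int)

    # equicorrelated multivariate normal via a shared factor:
    # z_r = sqrt(rho) * u + sqrt(1-rho) * e_r  has pairwise corr rho
    rho, mu, sd = scenario.signal_corr, scenario.signal_mean, scenario.signal_sd
    reps: list[list[GenomicInterval]] = [[] for _ in range(n_reps)]
    for si in keep_idx:
        site = true_sites[int(si)]
        reproducible = rng.random() < scenario.reproducible_fraction
        if reproducible:
            shared = rng.standard_normal()
            eps = rng.standard_normal(n_reps)
            lat = mu + sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps)
        else:
            lat = rng.standard_normal(n_reps)
        # provenance tag in the name records which mixture component the
        # site's scores came from, so calibration is checkable downstream
        tag = "sig" if reproducible else "null"
        site = replace_name(site, f"{site.name}|{tag}")
        for r in range(n_reps):
            reps[r].append(_emit_peak(site, float(lat[r]), rng))

    chroms = sorted({iv.chrom for iv in true_sites}) or ["chr1"]
    out = []
    for r in range(n_reps):
        nrng = _rng(scenario.seed, "peaks", condition, 1000 + r)
        for j in range(scenario.n_noise_peaks_per_rep):
            chrom = chroms[int(nrng.integers(len(chroms)))]
            width = int(nrng.integers(scenario.site_width_min,
                                      scenario.site_width_max + 1))
            start = int(nrng.integers(0, scenario.chrom_length - width))
            iv = GenomicInterval(chrom, start, start + width, ".",
                                 name=f"noise_{condition}_r{r + 1}_{j + 1}")
            reps[r].append(_emit_peak(iv, float(nrng.standard_normal()), nrng))
        out.append(IntervalSet(
            reps[r], sample_id=f"{condition}_rep{r + 1}",
            condition=condition).sorted())
    return out


def simulate_background(annotation: GenomeAnnotation,
                        scenario: SyntheticScenario) -> IntervalSet:
    """Uniformly placed background intervals, Poisson in number.

    Emulates the non-specific signal captured by a size-matched input or
    pooled IgG control; expected count = ``background_rate`` per kb of genome.
    """
    rng = _rng(scenario.seed, "background")
    genome_kb = sum(annotation.chrom_sizes.values()) / 1000.0
    n = int(rng.poisson(scenario.background_rate * genome_kb))
    chroms = sorted(annotation.chrom_sizes)
    ivs = []
    for j in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(scenario.site_width_min,
                                 scenario.site_width_max + 1))
        start = int(rng.integers(
            0, annotation.chrom_sizes[chrom] - width))
        ivs.append(GenomicInterval(chrom, start, start + width, ".",
                                   name=f"bg{j + 1:05d}"))
    return IntervalSet(ivs, sample_id="background").sorted()


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _rna_to_dna(motif: str) -> str:
    return motif.upper().replace("U", "T")


def simulate_sequences(footprints: IntervalSet,
                       scenario: SyntheticScenario) -> list[tuple[str, str]]:
    """One uniform-composition DNA sequence per footprint, motifs planted.

    The background-expected occurrence count of a k-mer in a sequence of
    length L is (L-k+1)/4^k; on top of the occurrences arising by chance,
    Poisson((enrichment-1) x expected) extra motif copies are written at
    random positions so the total occurrence rate is ``motif_enrichment``
    times the background rate.  Motifs in the RNA alphabet are mapped U->T.
    Returns ``(name, sequence)`` pairs.
    """
    rng = _rng(scenario.seed, "sequences")
    motif = _rna_to_dna(scenario.motif)
    k = len(motif)
    alphabet = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    for i, iv in enumerate(footprints):
        L = len(iv)
        if L < k:
            raise ValueError(
                f"footprint {iv.name or i} shorter than motif ({L} < {k})")
        seq = rng.choice(alphabet, size=L)
        expected = (L - k + 1) / 4 ** k
        n_plant = int(rng.poisson((scenario.motif_enrichment - 1.0) * expected))
        for _ in range(n_plant):
            pos = int(rng.integers(0, L - k + 1))
            seq[pos:pos + k] = list(motif)
        name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        records.append((name, "".join(seq)))
    return records


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

def simulate_assay_tables(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Junction-count, Ct, and band-intensity tables with group structure.

    Junction counts: per sample, inclusion reads ~ Binomial(depth, p) where
    p is the read-level inclusion probability implied by the group PSI and
    the effective lengths (length normalization applied in reverse), so the
    length-normalized PSI estimator recovers the planted group value.

    Ct table: reference Ct fixed, target Ct shifted per group by
    ``ct_shift_by_group`` (fold change 2^-shift) plus Gaussian noise.

    Band intensities: product A / product B split by the group PSI with
    multiplicative lognormal noise of coefficient of variation ``band_cv``.
    """
    if scenario.junction_depth < 1:
        raise ValueError("junction_depth must be >= 1")
    rng = _rng(scenario.seed, "assays")
    l_i, l_s = scenario.inclusion_len, scenario.skipping_len

    jrows, crows, brows = [], [], []
    for group in sorted(scenario.psi_by_group):
        psi = scenario.psi_by_group[group]
        shift = scenario.ct_shift_by_group.get(group, 0.0)
        # read-level inclusion probability implied by PSI and lengths
        denom = psi * l_i + (1 - psi) * l_s
        p_read = psi * l_i / denom if denom > 0 else 0.0
        for s in range(scenario.n_samples_per_group):
            sample = f"{group}_{s + 1}"
            inc = int(rng.binomial(scenario.junction_depth, p_read))
            jrows.append(dict(
                sample=sample, group=group, event="event1",
                inclusion=inc, skipping=scenario.junction_depth - inc,
                inclusion_len=l_i, skipping_len=l_s))
            ct_ref = scenario.ct_reference + rng.normal(0, scenario.ct_noise_sd)
            ct_tgt = (scenario.ct_reference + 2.0 + shift
                      + rng.normal(0, scenario.ct_noise_sd))
            crows.append(dict(sample=sample, group=group,
                              ct_target=round(float(ct_tgt), 4),
                              ct_reference=round(float(ct_ref), 4)))
            total = 1000.0 * float(np.exp(
                rng.normal(0, np.sqrt(np.log(1 + scenario.band_cv ** 2)))))
            brows.append(dict(sample=sample, group=group,
                              product_a=round(total * psi, 3),
                              product_b=round(total * (1 - psi), 3)))
    return (pd.DataFrame(jrows), pd.DataFrame(crows), pd.DataFrame(brows))


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records
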