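"""Seeded generators for synthetic study inputs.

Real inputs to the pipeline — centerline pore profiles from
electrostatics calculations, spliced RNA-seq alignments, and a
per-animal stroke cohort — are either unpublished or impractical to
ship, so every analysis stage here has a paired generator that emits
data with the statistical structure the stage assumes:

* :func:`gen_seam_profiles` builds per-seam r(z)/V(z) profiles whose
  group means hit specified isoform archetype targets (bottleneck
  radius, bottleneck potential, potential span) exactly at zero jitter;
* :func:`gen_cohort` builds an animal cohort with a planted
  isoform-1-linked edema/infarct/neuroscore effect and a severe-
  hemorrhage subgroup (> 5 mm³) that alone carries the
  hemorrhage-isoform association;
* :func:`gen_spliced_reads` builds a toy genome with a single-exon gene
  and paired-end alignments in which a chosen fraction of fragments
  span a planted intron with chosen donor/acceptor dinucleotides, with
  SAM flags consistent with the gene strand and library protocol.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .profile_model import AxialProfile, SeamSet

__all__ = [
    "ProfileArchetype",
    "ISO1_ARCHETYPE",
    "ISO2_ARCHETYPE",
    "gen_seam_profiles",
    "gen_cohort",
    "gen_spliced_reads",
]


# ---------------------------------------------------------------------------
# Seam profile generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileArchetype:
    """Target shape parameters for one isoform's seam profiles.

    Default targets are the published per-isoform group means: the
    canonical 35 kDa isoform 1 forms a wide, strongly charged pore
    (r_min 39.7 Å, V_bottleneck 159 kT/e, span 224 kT/e) and the 25 kDa
    isoform 2 a narrower pore with a weaker positive barrier
    (25.8 Å, 100.6 kT/e, span 297.7 kT/e).  ``well_depth`` (depth of
    the flanking negative wells, which let the span exceed the barrier
    height) is derived from span − V_bottleneck when None.
    """

    name: str
    target_r_min: float          # Å
    target_v_bottleneck: float   # kT/e
    target_span: float           # kT/e
    mouth_radius: float = 60.0   # Å, pore radius far from the constriction
    barrier_width_scale: float = 6.0   # Å, Gaussian width of the barrier
    well_depth: float | None = None    # kT/e
    seam_jitter: float = 0.0     # relative sd of per-seam multiplicative jitter

    def __post_init__(self) -> None:
        if not self.target_r_min > 0:
            raise ValueError("target_r_min must be > 0")
        if not self.barrier_width_scale > 0:
            raise ValueError("barrier_width_scale must be > 0")
        if self.seam_jitter < 0:
            raise ValueError("seam_jitter must be >= 0")
        if self.target_span < self.target_v_bottleneck:
            raise ValueError("target_span must be >= target_v_bottleneck")
        if self.mouth_radius <= self.target_r_min:
            raise ValueError("mouth_radius must exceed target_r_min")


ISO1_ARCHETYPE = ProfileArchetype(
    name="iso1", target_r_min=39.7, target_v_bottleneck=159.0, target_span=224.0
)
ISO2_ARCHETYPE = ProfileArchetype(
    name="iso2", target_r_min=25.8, target_v_bottleneck=100.6, target_span=297.7
)

_SEAM_COMBOS = (("A", "I"), ("A", "II"), ("B", "I"), ("B", "II"))

# grid/well geometry shared by all generated seams
_Z_HALF_EXTENT = 40.0   # Å
_DZ = 0.5               # Å
_WELL_CENTER = 25.0     # Å
_WELL_WIDTH = 3.0       # Å
_RADIUS_WIDTH = 8.0     # Å


def gen_seam_profiles(
    archetype: ProfileArchetype,
    n_seams: int = 4,
    seed: int | np.random.Generator | None = 0,
) -> SeamSet:
    """Generate up to four seam profiles matching an isoform archetype.

    The radius is a Gaussian constriction
    ``r(z) = R_mouth − (R_mouth − r_min)·exp(−z²/2σ_r²)`` and the
    potential a central Gaussian barrier of height ``V_bottleneck``
    flanked by two negative Gaussian wells whose amplitude is chosen so
    that the full span (max V − min V) hits the target.  Per-seam
    targets are jittered multiplicatively by ``seam_jitter`` (truncated
    normal factors, never below 5%); at zero jitter every seam
    reproduces the archetype targets to better than 1e-6 relative.
    """
    if not 1 <= n_seams <= len(_SEAM_COMBOS):
        raise ValueError(f"n_seams must lie in [1, {len(_SEAM_COMBOS)}], got {n_seams}")
    rng = np.random.default_rng(seed)
    z = np.arange(-_Z_HALF_EXTENT, _Z_HALF_EXTENT + _DZ / 2, _DZ)
    sigma_v = archetype.barrier_width_scale
    profiles = []
    for dimer, pore in _SEAM_COMBOS[:n_seams]:
        jit = np.maximum(1.0 + archetype.seam_jitter * rng.standard_normal(3), 0.05)
        r_min = archetype.target_r_min * jit[0]
        height = archetype.target_v_bottleneck * jit[1]
        if archetype.well_depth is None:
            span = archetype.target_span * jit[2]
        else:
            span = height + archetype.well_depth * jit[2]
        span = max(span, height)  # wells cannot have negative depth
        radius = archetype.mouth_radius - (archetype.mouth_radius - r_min) * np.exp(
            -(z**2) / (2.0 * _RADIUS_WIDTH**2)
        )
        barrier = height * np.exp(-(z**2) / (2.0 * sigma_v**2))
        # well amplitude chosen so that V(0) − V(±well_center) == span
        leak = height * np.exp(-(_WELL_CENTER**2) / (2.0 * sigma_v**2))
        amp = span - height + leak
        wells = amp * (
            np.exp(-((z - _WELL_CENTER) ** 2) / (2.0 * _WELL_WIDTH**2))
            + np.exp(-((z + _WELL_CENTER) ** 2) / (2.0 * _WELL_WIDTH**2))
        )
        profiles.append(
            AxialProfile(
                seam_id=f"{archetype.name}-{dimer}-{pore}",
                isoform_label=archetype.name,
                dimer=dimer,
                pore=pore,
                z=z,
                radius=radius,
                potential=barrier - wells,
            )
        )
    return SeamSet(tuple(profiles))


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

DEFAULT_EFFECTS = {
    "edema_volume": 12.0,     # mm³ per density unit of isoform 1
    "infarct_volume": 15.0,
    "neuroscore": -8.0,       # points per density unit (higher iso1 = worse)
}


def gen_cohort(
    n_animals: int = 50,
    effects: dict[str, float] | None = None,
    noise_sd: float = 4.0,
    severe_fraction: float = 0.15,
    severe_hemorrhage_slope: float = 4.0,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Generate a stroke cohort with a planted isoform-1 effect.

    Isoform densities are log-normal (claudin-5/β-actin ratios near 1).
    Edema and infarct volumes are linear in iso1 density plus Gaussian
    noise of sd ``noise_sd`` (mm³); the neuroscore decreases with iso1,
    is rounded and clamped to [0, 28].  A ``severe_fraction`` subgroup
    — the animals with the highest iso1 density — receives hemorrhage
    volumes strictly above 5 mm³ that increase with iso1 density at
    ``severe_hemorrhage_slope``; all other animals' hemorrhage is small
    (< 5 mm³) and independent of isoform expression, so the
    hemorrhage-isoform association is carried entirely by the severe
    subgroup.
    """
    if n_animals < 4:
        raise ValueError("n_animals must be >= 4")
    if not 0.0 <= severe_fraction <= 1.0:
        raise ValueError("severe_fraction must lie in [0, 1]")
    if effects is None:
        effects = DEFAULT_EFFECTS
    rng = np.random.default_rng(seed)
    iso1 = rng.lognormal(mean=0.0, sigma=0.4, size=n_animals)
    iso2 = rng.lognormal(mean=-0.2, sigma=0.4, size=n_animals)
    fragment = rng.lognormal(mean=-1.0, sigma=0.5, size=n_animals)

    def outcome(slope: float, base: float) -> np.ndarray:
        return base + slope * iso1 + noise_sd * rng.standard_normal(n_animals)

    edema = np.maximum(outcome(effects.get("edema_volume", 0.0), 5.0), 0.0)
    infarct = np.maximum(outcome(effects.get("infarct_volume", 0.0), 20.0), 0.0)
    neuro = np.clip(
        np.round(
            26.0
            + effects.get("neuroscore", 0.0) * (iso1 - 1.0)
            + 2.0 * rng.standard_normal(n_animals)
        ),
        0,
        28,
    )

    hemorrhage = np.minimum(np.abs(rng.normal(1.0, 0.8, size=n_animals)), 4.9)
    n_severe = int(round(severe_fraction * n_animals))
    if n_severe > 0:
        severe_idx = np.argsort(iso1)[-n_severe:]
        hemorrhage[severe_idx] = (
            5.2
            + severe_hemorrhage_slope * iso1[severe_idx]
            + np.abs(rng.normal(0.0, 0.5, size=n_severe))
        )
    return pd.DataFrame(
        {
            "animal_id": [f"animal{i:03d}" for i in range(n_animals)],
            "iso1_density": iso1,
            "iso2_density": iso2,
            "fragment_density": fragment,
            "infarct_volume": infarct,
            "edema_volume": edema,
            "hemorrhage_volume": hemorrhage,
            "neuroscore": neuro,
        }
    )


# ---------------------------------------------------------------------------
# Spliced-read generator
# ---------------------------------------------------------------------------

_CHROM = "chrT"


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def gen_spliced_reads(
    out_dir: str | os.PathLike,
    genome_length: int = 10_000,
    junction: tuple[int, int, str] = (2001, 2500, "GC-AG"),
    gene_strand: str = "-",
    library_type: str = "RF",
    n_pairs: int = 100,
    junction_fraction: float = 0.5,
    read_length: int = 50,
    min_overhang: int = 5,
    max_overhang: int | None = None,
    contamination_fraction: float = 0.0,
    mapq: int = 60,
    seed: int | np.random.Generator | None = 0,
) -> dict[str, Path]:
    """Write a toy genome, single-exon gene annotation and paired reads.

    ``junction`` is (intron_start, intron_end, "donor-acceptor") with
    1-based inclusive intron coordinates and the motif given on the
    transcript strand of ``gene_strand``.  A ``junction_fraction`` of
    the pairs carries a read whose CIGAR skips exactly the planted
    intron (overhangs drawn uniformly in [min_overhang, max_overhang]);
    the rest are unspliced pairs upstream of the intron.  Fragment
    orientations (and hence the 99/147 vs 83/163 flag pairs) follow the
    gene strand under the stated library protocol, except for a
    ``contamination_fraction`` of spliced pairs planted antisense.
    Returns paths: {"sam", "fasta", "gff3"}.
    """
    start, end, motif = junction
    donor, _, acceptor = motif.partition("-")
    if len(donor) != 2 or len(acceptor) != 2:
        raise ValueError(f"motif must be 'XY-ZW', got {motif!r}")
    if not (1 <= start <= end <= genome_length) or end - start + 1 < 4:
        raise ValueError("junction not plantable at the requested coordinates")
    if gene_strand not in ("+", "-"):
        raise ValueError("gene_strand must be '+' or '-'")
    if library_type not in ("unstranded", "FR", "RF"):
        raise ValueError(f"unknown library_type {library_type!r}")
    if max_overhang is None:
        max_overhang = read_length - min_overhang
    if not 1 <= min_overhang <= max_overhang <= read_length - 1:
        raise ValueError("invalid overhang bounds")
    if start - read_length - 300 < 1 or end + read_length + 200 > genome_length:
        raise ValueError("junction too close to the genome ends for read placement")

    rng = np.random.default_rng(seed)
    genome = rng.choice(list("ACGT"), size=genome_length)
    # plant the donor/acceptor dinucleotides on the reference strand
    if gene_strand == "+":
        plus_first2, plus_last2 = donor, acceptor
    else:
        plus_first2, plus_last2 = _revcomp(acceptor), _revcomp(donor)
    genome[start - 1 : start + 1] = list(plus_first2)
    genome[end - 2 : end] = list(plus_last2)
    genome_str = "".join(genome)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "genome.fa"
    fasta_path.write_text(
        f">{_CHROM}\n"
        + "\n".join(genome_str[i : i + 70] for i in range(0, genome_length, 70))
        + "\n"
    )

    gene_start = max(1, start - 500)
    gene_end = min(genome_length, end + 500)
    gff3_path = out_dir / "gene.gff3"
    attrs_gene = "ID=gene1;Name=toy_single_exon_gene"
    gff3_path.write_text(
        "##gff-version 3\n"
        f"{_CHROM}\tsynthetic\tgene\t{gene_start}\t{gene_end}\t.\t{gene_strand}\t.\t{attrs_gene}\n"
        f"{_CHROM}\tsynthetic\tmRNA\t{gene_start}\t{gene_end}\t.\t{gene_strand}\t.\tID=tx1;Parent=gene1\n"
        f"{_CHROM}\tsynthetic\texon\t{gene_start}\t{gene_end}\t.\t{gene_strand}\t.\tID=exon1;Parent=tx1\n"
    )

    n_spliced = int(round(n_pairs * junction_fraction))
    intron_len = end - start + 1
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": _CHROM, "LN": genome_length}],
    }

    def fragment_strand(contaminated: bool) -> str:
        if library_type == "unstranded":
            return "+" if rng.random() < 0.5 else "-"
        frag = gene_strand if library_type == "FR" else ("-" if gene_strand == "+" else "+")
        if contaminated:
            frag = "-" if frag == "+" else "+"
        return frag

    def make_read(qname, pos0, cig, seq, flag, mate_pos0, tlen):
        a = pysam.AlignedSegment()
        a.query_name = qname
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos0
        a.mapping_quality = mapq
        a.cigarstring = cig
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.next_reference_id = 0
        a.next_reference_start = mate_pos0
        a.template_length = tlen
        a.set_tag("NH", 1)
        return a

    sam_path = out_dir / "reads.sam"
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for i in range(n_pairs):
            spliced = i < n_spliced
            contaminated = spliced and rng.random() < contamination_fraction
            frag = fragment_strand(contaminated)
            if spliced:
                o = int(rng.integers(min_overhang, max_overhang + 1))
                left_pos = start - o  # 1-based start of the spliced read
                cig = f"{o}M{intron_len}N{read_length - o}M"
                seq = (
                    genome_str[left_pos - 1 : start - 1]
                    + genome_str[end : end + read_length - o]
                )
                right_pos = end + read_length - o + int(rng.integers(10, 100))
                right_seq = genome_str[right_pos - 1 : right_pos - 1 + read_length]
                right_cig = f"{read_length}M"
                span = right_pos + read_length - left_pos
            else:
                left_pos = int(rng.integers(max(1, start - 450), start - read_length - 200))
                cig = f"{read_length}M"
                seq = genome_str[left_pos - 1 : left_pos - 1 + read_length]
                right_pos = left_pos + 150
                right_seq = genome_str[right_pos - 1 : right_pos - 1 + read_length]
                right_cig = f"{read_length}M"
                span = right_pos + read_length - left_pos
            qname = f"pair{i:05d}"
            if frag == "+":
                left_flag, right_flag = 99, 147   # read1 forward, read2 reverse
            else:
                left_flag, right_flag = 163, 83   # read2 forward, read1 reverse
            sam.write(
                make_read(qname, left_pos - 1, cig, seq, left_flag, right_pos - 1, span)
            )
            sam.write(
                make_read(qname, right_pos - 1, right_cig, right_seq, right_flag,
                          left_pos - 1, -span)
            )
    return {"sam": sam_path, "fasta": fasta_path, "gff3": gff3_path}
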