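import numpy as np
import pytest
from hypothesis import settings

from cldn5kit.profile_model import AxialProfile

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_profile(z, radius, potential, seam_id="s1", isoform="iso1",
                 dimer="A", pore="I"):
    return AxialProfile(
        seam_id=seam_id, isoform_label=isoform, dimer=dimer, pore=pore,
        z=np.asarray(z, float), radius=np.asarray(radius, float),
        potential=np.asarray(potential, float),
    )


@pytest.fixture
def triangle_profile():
    """V(z) = max(10 - 2|z|, 0) on z = -10..10 step 1, constant radius."""
    z = np.arange(-10.0, 11.0)
    v = np.maximum(10.0 - 2.0 * np.abs(z), 0.0)
    return make_profile(z, np.full(z.size, 5.0), v)


def write_sam(path, records, chrom="chrT", length=100_000):
    """Write a minimal SAM file.

    Each record is (qname, flag, pos1, mapq, cigar, tags) with 1-based
    pos; seq/qual are written as '*' placeholders of matching length.
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for qname, flag, pos1, mapq, cigar, *rest in records:
        tags = rest[0] if rest else []
        fields = [qname, str(flag), chrom, str(pos1), str(mapq), cigar,
                  "*", "0", "0", "*", "*"] + list(tags)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path
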