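import pytest

from repeatlens.fragio import Peak, PeakTable
from repeatlens.repeatcall import Calibration
from repeatlens import synthgen


@pytest.fixture
def cal() -> Calibration:
    """Calibration anchored on a 20-repeat allele at 160 bp (3 bp unit)."""
    return Calibration(reference_repeat=20, reference_size_bp=160.0, repeat_unit_bp=3)


def table_from_repeats(repeat_heights, cal, sample_id="s1", locus="HTT", day=None):
    """Build a PeakTable whose peaks sit exactly on the repeat grid."""
    peaks = [
        Peak(
            size_bp=cal.reference_size_bp
            + (r - cal.reference_repeat) * cal.repeat_unit_bp,
            height=float(h),
        )
        for r, h in repeat_heights.items()
    ]
    return PeakTable(sample_id=sample_id, locus=locus, peaks=peaks, day=day)


@pytest.fixture(scope="session")
def u2os_dir(tmp_path_factory):
    """Packaged biallelic fixture, rendered once per session with seed 1."""
    out = tmp_path_factory.mktemp("u2os_fixture")
    synthgen.make_fixture_u2os(out, seed=1)
    return out


@pytest.fixture(scope="session")
def xlink_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("xlink_fixture")
    return synthgen.make_xlink_fixture(out)
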