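import json
from pathlib import Path

import pytest

from croma.alignment_io import SiteAlignment
from croma.fixtures import make_fixtures
from croma.probe_model import ProbeDesignOption, ProbeType

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The deterministic toy fixture bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    truth = make_fixtures(FIXTURE_SEED, out)
    return truth


@pytest.fixture(scope="session")
def bundle_dir(bundle):
    return Path(bundle["paths"]["reference"]).parent


def make_site(ref_probe: str, rows: dict[str, str],
              insertion: dict[str, bool] | None = None,
              option: ProbeDesignOption | None = None) -> SiteAlignment:
    """Hand-built site alignment: ``ref_probe`` is the probe window and
    a CG dinucleotide is appended as the target CpG columns."""
    option = option or ProbeDesignOption(ProbeType.II, "+")
    window = len(ref_probe)
    ref = ref_probe + "CG"
    full_rows = {"ref": ref}
    for name, row in rows.items():
        if len(row) == window:
            row = row + "CG"
        full_rows[name] = row
    ins = {s: False for s in full_rows}
    ins.update(insertion or {})
    return SiteAlignment(
        chrom="chrT", cpg_position=window, option=option,
        window=(0, window + 2), probe_interval=(0, window),
        reference_seq=ref, reference_species="ref",
        species_rows=full_rows, insertion=ins)
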