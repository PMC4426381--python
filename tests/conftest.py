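"""Shared fixtures: one standard synthetic study per session, written to
disk, plus helpers for constructing tiny hand-made inputs."""

import pytest

from tomindel.synthetic_data import SyntheticConfig, generate_dataset

STANDARD_SEED = 1234


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """The standard fixture: default generator conditions, files on disk."""
    out = tmp_path_factory.mktemp("standard_dataset")
    return generate_dataset(STANDARD_SEED, out_dir=str(out))


@pytest.fixture(scope="session")
def pseudo_panel():
    """A large frameshift-candidate panel spanning every category,
    in memory (no background noise files needed)."""
    plan = {
        "genuine": {
            "truncated_major": 30,
            "altered_C_terminal": 30,
            "extended_C_terminal": 20,
        },
        "pseudo_outside": 40,
        "pseudo_border": 30,
        "pseudo_inframe": 25,
        "pseudo_internal_stop": 25,
        "het": 0,
        "silent": 0,
    }
    cfg = SyntheticConfig(
        fs_plan=plan,
        with_markers=False,
        third_line=False,
        segments=(),
        n_accessions=0,
    )
    return generate_dataset(99, cfg)
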