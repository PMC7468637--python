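import numpy as np
import pandas as pd
import pytest

from vdodge.body import Anthropometrics
from vdodge.effects import default_effect_table


@pytest.fixture(scope="session")
def calibrated_table():
    """Study-derived effect table with solved contact postures."""
    return default_effect_table().calibrate()


@pytest.fixture(scope="session")
def zero_noise_table():
    """Noise-free variant: every SD zero, same cell means."""
    return default_effect_table().scaled(0.0).calibrate()


@pytest.fixture(scope="session")
def ref_female():
    return Anthropometrics.reference("female")


@pytest.fixture(scope="session")
def ref_male():
    return Anthropometrics.reference("male")


def make_long_table(
    rng,
    n_per_sex=6,
    persp_effect=0.0,
    ih_effects=(0.0, 0.0, 0.0),
    interaction=None,
    subject_sd=1.0,
    noise_sd=0.5,
):
    """Balanced 2x3 mixed-design long table with known generating effects.

    ``interaction[(p, ih)]`` adds a cell-specific shift on top of the
    additive structure.
    """
    rows = []
    for s in range(2 * n_per_sex):
        sex = "male" if s < n_per_sex else "female"
        base = rng.normal(0.0, subject_sd)
        for p in ("first", "third"):
            for i, h in enumerate(("IH1", "IH2", "IH3")):
                val = base + (persp_effect if p == "first" else 0.0) + ih_effects[i]
                if interaction:
                    val += interaction.get((p, h), 0.0)
                rows.append(
                    dict(
                        subject_id=f"S{s:02d}",
                        sex=sex,
                        perspective=p,
                        impact_height=h,
                        val=val + rng.normal(0.0, noise_sd),
                    )
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
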