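import numpy as np
import pandas as pd
import pytest

from gutlipid import simulate as sim


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    design = sim.CohortDesign(seed=11)
    abundance, lipid, metadata, panel, ledger = sim.generate_cohort(design)
    return {
        "design": design,
        "abundance": abundance,
        "lipid": lipid,
        "metadata": metadata,
        "panel": panel,
        "ledger": ledger,
    }


@pytest.fixture()
def paired_metadata():
    """Small two-group, two-time-point sample sheet."""

    def build(n_per_group=6, groups=("probiotic", "placebo")):
        rows = []
        i = 1
        for g in groups:
            for _ in range(n_per_group):
                for t in (1, 2):
                    rows.append(
                        {
                            "sample_id": f"S{i:02d}_T{t}",
                            "subject": f"S{i:02d}",
                            "timepoint": t,
                            "group": g,
                        }
                    )
                i += 1
        return pd.DataFrame(rows).set_index("sample_id")

    return build


def make_table(metadata, values):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=metadata.index,
        columns=[f"f{j}" for j in range(values.shape[1])],
    )
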