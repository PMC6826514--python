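import numpy as np
import pandas as pd
import pytest

# the worked-example replicate vectors: three genes with identical mean 1.0
# but contrasting variability and coordination
G1 = np.array([0.95, 0.98, 1.01, 1.06])
G2 = np.array([1.05, 1.01, 1.00, 0.94])
G3 = np.array([1.50, 1.10, 0.90, 0.50])


@pytest.fixture
def worked_example():
    return G1, G2, G3


def make_spot_table(
    spots,
    conditions=("c1",),
    replicates=2,
    foreground=1000.0,
    background=100.0,
):
    """Build a complete-design raw spot table programmatically.

    ``spots`` maps spot_id -> dict with optional keys transcript_id,
    is_control, is_corrupted (sample index where corruption occurs),
    low_signal (sample index where foreground drops below 2x background),
    foreground, background.
    """
    rows = []
    sample = 0
    samples = [(c, r) for c in conditions for r in range(1, replicates + 1)]
    for sid, props in spots.items():
        for sample, (cond, rep) in enumerate(samples):
            fg = props.get("foreground", foreground)
            bg = props.get("background", background)
            if props.get("low_signal") == sample:
                fg = 1.99 * bg
            rows.append(
                {
                    "spot_id": sid,
                    "transcript_id": props.get("transcript_id", sid.split("_")[0]),
                    "condition": cond,
                    "replicate": rep,
                    "foreground": fg,
                    "background": bg,
                    "is_control": bool(props.get("is_control", False)),
                    "is_corrupted": props.get("is_corrupted") == sample,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def spot_table_builder():
    return make_spot_table


def normalized_frame(values_by_gene, condition="c1", redundancy=None):
    """Tidy normalized table from gene -> replicate-values (or spot -> values)."""
    rows = []
    for gene, vals in values_by_gene.items():
        spots = vals if isinstance(vals, dict) else {f"{gene}_s1": vals}
        for sid, arr in spots.items():
            for rep, v in enumerate(arr, start=1):
                rows.append(
                    {
                        "spot_id": sid,
                        "transcript_id": gene,
                        "condition": condition,
                        "replicate": rep,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def normalized_builder():
    return normalized_frame
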