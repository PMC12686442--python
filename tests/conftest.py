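import numpy as np
import pandas as pd
import pytest

from cmaflux import CmaNetworkTable, ExpressionMatrix, QuantMatrix


@pytest.fixture(scope="session")
def default_network() -> CmaNetworkTable:
    return CmaNetworkTable.default()


@pytest.fixture()
def two_gene_network() -> CmaNetworkTable:
    return CmaNetworkTable.from_frame(
        pd.DataFrame(
            {
                "symbol": ["LAMP2", "GENE_NEG"],
                "role": ["effector", "negative_modulator"],
                "direction": [1, -1],
                "weight": [2, 1],
            }
        )
    )


def expression(data: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(data, index=samples).T, scale="log_normalized")


@pytest.fixture()
def small_quant() -> QuantMatrix:
    """3 proteins x 3+3 unpaired samples on the log2 scale."""
    intens = pd.DataFrame(
        {
            "c1": [10.0, 12.0, 8.0],
            "c2": [10.1, 12.0, 8.1],
            "c3": [9.9, 12.0, 7.9],
            "n1": [11.0, 12.0, 8.2],
            "n2": [11.1, 12.0, 8.0],
            "n3": [10.9, 12.0, 8.1],
        },
        index=["P1", "P2", "P3"],
    )
    design = pd.DataFrame(
        {
            "condition": ["control"] * 3 + ["NL"] * 3,
        },
        index=["c1", "c2", "c3", "n1", "n2", "n3"],
    ).rename_axis("sample")
    return QuantMatrix(intensities=intens, design=design, scale="log2")
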