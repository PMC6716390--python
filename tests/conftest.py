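import numpy as np
import pandas as pd
import pytest

from lexacq import Corpus, PredictorTable, TokenMapper, parse_chat_lite


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Hand-written corpus with known counts (adult + child lines)."""
    lines = [
        "ADU\tdog",                    # solo dog
        "ADU\tthe big dog",            # final dog
        "ADU\tdog dogs cat",           # dog x2 (inflected), final cat
        "ADU\torange orange",          # polysemous, final orange
        "CHI\tdog dog dog",            # child speech: ignored
        "ADU\tthe cat sat",
    ]
    return parse_chat_lite(lines)


@pytest.fixture
def tiny_mapper() -> TokenMapper:
    return TokenMapper(
        form_to_item={"dog": "dog", "cat": "cat", "the": "the",
                      "big": "big", "sat": "sat"},
        inflection_map={"dogs": "dog"},
        polysemy_map={"orange": ["orange_color", "orange_fruit"]},
    )


@pytest.fixture
def tiny_items() -> pd.Index:
    return pd.Index(["dog", "cat", "the", "big", "sat",
                     "orange_color", "orange_fruit"], name="item_id")


def make_predictor_table(df: pd.DataFrame, **kw) -> PredictorTable:
    return PredictorTable(df, **kw)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
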