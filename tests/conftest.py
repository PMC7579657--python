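import numpy as np
import pandas as pd
import pytest

from emomine import (
    TransactionSet,
    bundled_lexicon_path,
    default_catalog,
    load_lexicon,
)

CATALOG = default_catalog()


@pytest.fixture(scope="session")
def lexicon():
    lex, _ = load_lexicon(bundled_lexicon_path())
    return lex


@pytest.fixture(scope="session")
def catalog():
    return CATALOG


def ts_from_rows(rows):
    """Build a TransactionSet from [(channel, {items}), ...]."""
    items = CATALOG.items
    mat = np.zeros((len(rows), len(items)), dtype=np.int8)
    channels = []
    for i, (channel, present) in enumerate(rows):
        channels.append(channel)
        for item in present:
            mat[i, items.index(item)] = 1
    frame = pd.DataFrame(mat, columns=list(items))
    frame.insert(0, "channel", channels)
    frame.insert(0, "post_id", [f"p{i}" for i in range(len(rows))])
    return TransactionSet(items=items, frame=frame)


def ts_from_column_counts(n_posts, column_counts, channel="blog"):
    """Transactions with exact column sums; items fill from row 0 down.

    ``column_counts`` maps item -> count, or item -> {channel: count} to
    split an item's mentions across channels (channel blocks are laid out
    in catalog channel order, sized by the largest per-channel totals).
    """
    from emomine.lexicon import CHANNELS

    items = CATALOG.items
    per_channel = any(isinstance(v, dict) for v in column_counts.values())
    if not per_channel:
        mat = np.zeros((n_posts, len(items)), dtype=np.int8)
        for item, count in column_counts.items():
            mat[:count, items.index(item)] = 1
        channels = [channel] * n_posts
    else:
        # contiguous channel blocks, each large enough for its counts
        block = {
            ch: max(
                [v.get(ch, 0) if isinstance(v, dict) else 0 for v in column_counts.values()]
                + [0]
            )
            for ch in CHANNELS
        }
        n_posts = max(n_posts, sum(block.values()))
        channels = []
        offsets = {}
        for ch in CHANNELS:
            offsets[ch] = len(channels)
            channels.extend([ch] * block[ch])
        channels.extend([CHANNELS[0]] * (n_posts - len(channels)))
        mat = np.zeros((n_posts, len(items)), dtype=np.int8)
        for item, counts in column_counts.items():
            if isinstance(counts, dict):
                for ch, count in counts.items():
                    off = offsets[ch]
                    mat[off : off + count, items.index(item)] = 1
            else:
                mat[:counts, items.index(item)] = 1
    frame = pd.DataFrame(mat, columns=list(items))
    frame.insert(0, "channel", channels)
    frame.insert(0, "post_id", [f"p{i}" for i in range(n_posts)])
    return TransactionSet(items=items, frame=frame)


def brute_force_frequent(matrix, item_names, min_support):
    """Independent oracle: enumerate every subset of the active items."""
    from itertools import combinations

    n = matrix.shape[0]
    active = [j for j in range(matrix.shape[1]) if matrix[:, j].any()]
    out = {}
    for k in range(1, len(active) + 1):
        for combo in combinations(active, k):
            sup = matrix[:, combo].all(axis=1).sum() / n
            if sup >= min_support:
                out[frozenset(item_names[j] for j in combo)] = sup
    return out
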