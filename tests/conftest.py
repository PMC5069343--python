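import numpy as np
import pytest

from bsmap.template import BodyTemplate, make_synthetic_template


@pytest.fixture(scope="session")
def humanoid64() -> BodyTemplate:
    return make_synthetic_template(64, 64, "humanoid")


@pytest.fixture(scope="session")
def rect32() -> BodyTemplate:
    return make_synthetic_template(32, 32, "rectangle")


def full_single_view(size: int) -> BodyTemplate:
    """Fully-masked single (front) view template, for calibration tests."""
    return BodyTemplate(np.ones((size, size), dtype=bool),
                        np.ones((size, size), dtype=np.uint8),
                        name=f"full-{size}")


@pytest.fixture(scope="session")
def full16() -> BodyTemplate:
    return full_single_view(16)


def flood_fill_components(binary: np.ndarray, view_labels: np.ndarray,
                          connectivity: int) -> list[frozenset]:
    """Brute-force flood-fill connected components, per view.

    Independent oracle for label_connected: explicit stack-based fill
    over the chosen adjacency, views kept separate.
    """
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            view = view_labels[r0, c0]
            comp = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < h and 0 <= cc < w and binary[rr, cc]
                            and not seen[rr, cc] and view_labels[rr, cc] == view):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def balanced_anova_oracle(scores) -> dict:
    """Textbook balanced two-way sums-of-squares decomposition."""
    from scipy import stats as sps
    y = scores.pivot_table(index="stimulus_type", columns="stimulus_location",
                           values="score", aggfunc=list)
    a_levels, b_levels = list(y.index), list(y.columns)
    a, b = len(a_levels), len(b_levels)
    n = len(y.iloc[0, 0])
    data = np.array([[y.loc[ai, bi] for bi in b_levels] for ai in a_levels],
                    dtype=float)  # (a, b, n)
    grand = data.mean()
    mean_ab = data.mean(axis=2)
    mean_a = data.mean(axis=(1, 2))
    mean_b = data.mean(axis=(0, 2))
    ss_a = n * b * np.sum((mean_a - grand) ** 2)
    ss_b = n * a * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_w = np.sum((data - mean_ab[:, :, None]) ** 2)
    df_a, df_b = a - 1, b - 1
    df_ab, df_w = df_a * df_b, a * b * (n - 1)
    out = {}
    for eff, ss, df in (("stimulus", ss_a, df_a), ("location", ss_b, df_b),
                        ("interaction", ss_ab, df_ab)):
        F = (ss / df) / (ss_w / df_w)
        out[f"F_{eff}"] = F
        out[f"p_{eff}"] = float(sps.f.sf(F, df, df_w))
        out[f"ss_{eff}"] = ss
    out["ss_within"] = ss_w
    out["ss_total"] = float(np.sum((data - grand) ** 2))
    return out
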