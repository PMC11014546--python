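"""Small deterministic synthetic screens with documented ground truth.

These generators back the test suite, the CLI ``fixture`` subcommand and the
worked examples: every table is reproducible from its seed and records which
perturbations are truly active (or which labels cohere) by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import ProfileTable, from_dataframe

FIXTURE_KINDS = ("toy_screen", "null_screen", "multilabel_toy")


def _assemble(meta: dict[str, list], X: np.ndarray) -> ProfileTable:
    feats = pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(X.shape[1])])
    df = pd.concat([pd.DataFrame(meta), feats], axis=1)
    return from_dataframe(df)


def toy_screen(
    seed: int = 0,
    n_active: int = 5,
    n_inactive: int = 5,
    n_replicates: int = 3,
    n_controls: int = 12,
    n_features: int = 100,
    shift: float = 2.0,
) -> ProfileTable:
    """A screen with known actives: ``n_active`` perturbations shifted by
    ``shift`` SD in every feature, the rest drawn from the control
    distribution. Active perturbations are named ``pert_01..``, and the
    ``Metadata_active`` column records the ground truth."""
    rng = np.random.default_rng(seed)
    names, active, rows = [], [], []
    n_pert = n_active + n_inactive
    for i in range(n_pert):
        is_active = i < n_active
        loc = shift if is_active else 0.0
        rows.append(rng.normal(loc, 1.0, size=(n_replicates, n_features)))
        names += [f"pert_{i + 1:02d}"] * n_replicates
        active += [is_active] * n_replicates
    rows.append(rng.normal(0.0, 1.0, size=(n_controls, n_features)))
    names += ["control"] * n_controls
    active += [False] * n_controls
    X = np.vstack(rows)
    return _assemble(
        {
            "Metadata_pert": names,
            "Metadata_control": [n == "control" for n in names],
            "Metadata_active": active,
        },
        X,
    )


def null_screen(
    seed: int = 0,
    n_perturbations: int = 10,
    n_replicates: int = 3,
    n_controls: int = 12,
    n_features: int = 100,
) -> ProfileTable:
    """All rows i.i.d. standard normal: ground truth is 'nothing active'."""
    return toy_screen(
        seed=seed,
        n_active=0,
        n_inactive=n_perturbations,
        n_replicates=n_replicates,
        n_controls=n_controls,
        n_features=n_features,
    )


def multilabel_toy(seed: int = 0, n_features: int = 30) -> tuple[ProfileTable, pd.DataFrame]:
    """8 consensus perturbations and 3 labels; ``pert_7`` carries two labels.

    Labels A, B, C each shift a disjoint feature block, so members of a label
    cluster tightly and labels are mutually distinguishable. Returns the
    consensus table and a long-format (perturbation, label) annotation frame.
    """
    rng = np.random.default_rng(seed)
    block = n_features // 3
    signatures = {
        "A": (0, block),
        "B": (block, 2 * block),
        "C": (2 * block, n_features),
    }
    annotations = [
        ("pert_1", "A"), ("pert_2", "A"), ("pert_3", "B"), ("pert_4", "B"),
        ("pert_5", "C"), ("pert_6", "C"), ("pert_7", "A"), ("pert_7", "C"),
        # pert_8 is unannotated background
    ]
    perts = [f"pert_{i}" for i in range(1, 9)]
    label_of: dict[str, list[str]] = {p: [] for p in perts}
    for p, t in annotations:
        label_of[p].append(t)
    X = rng.normal(0.0, 0.3, size=(len(perts), n_features))
    for i, p in enumerate(perts):
        for t in label_of[p]:
            lo, hi = signatures[t]
            X[i, lo:hi] += 5.0
    table = _assemble({"Metadata_pert": perts}, X)
    ann = pd.DataFrame(annotations, columns=["perturbation_id", "label"])
    return table, ann


def make_fixture(kind: str, seed: int = 0):
    """Dispatch by fixture kind (see :data:`FIXTURE_KINDS`)."""
    if kind == "toy_screen":
        return toy_screen(seed=seed)
    if kind == "null_screen":
        return null_screen(seed=seed)
    if kind == "multilabel_toy":
        return multilabel_toy(seed=seed)
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
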