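"""Alphabet-transfer experiment: train on a restricted-alphabet screen,
test on an expanded-alphabet screen under the same ground-truth landscape.

This reproduces, at simulator scale, the headline transfer setting: a
model trained on pairs from the restricted library (Z-A over 8 amino
acids, Z-B over 5) scores held-out pairs from the expanded 11-amino-acid
library, stratified by how many test residues fall outside the training
alphabets (novel-amino-acid bins 0, 1, 2, 3, 4+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coevoscreen.interaction_model import (
    EvalReport,
    ModelConfig,
    PhysicochemicalEmbedder,
    assemble_dataset,
    evaluate,
    train_model,
)
from coevoscreen.library_design import DegenerateCodon, LibraryDesign, ll2_design
from coevoscreen.pair_enrichment import filter_pairs, pool_counts
from coevoscreen.screen_simulator import (
    SelectionConfig,
    build_landscape,
    simulate_screen,
)


def restricted_design() -> LibraryDesign:
    """Restricted-alphabet training design on the expanded library's
    position geometry: Z-A 4 positions over {F,H,I,K,L,N,Q,Y}, Z-B 4
    positions over {F,I,L,M,V}."""
    import warnings

    base = ll2_design()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return LibraryDesign(
            name="LL1-restricted",
            scaffold_A=base.scaffold_A,
            scaffold_B=base.scaffold_B,
            positions_A=list(base.positions_A),
            positions_B=list(base.positions_B),
            codons_A=[DegenerateCodon("HWW")] * 4,
            codons_B=[DegenerateCodon("DTK")] * 4,
        )


def union_alphabets(d1: LibraryDesign, d2: LibraryDesign) -> tuple[list[str], list[str]]:
    """Per-position alphabet unions of two designs with equal geometry."""
    ua = ["".join(sorted(set(a) | set(b)))
          for a, b in zip(d1.alphabets_A, d2.alphabets_A)]
    ub = ["".join(sorted(set(a) | set(b)))
          for a, b in zip(d1.alphabets_B, d2.alphabets_B)]
    return ua, ub


@dataclass
class TransferSettings:
    """Scaled-for-CPU experiment sizes; model defaults in ModelConfig are
    overridden here to keep a single-CPU run in minutes."""

    planted: dict = field(default_factory=lambda: {(2, 4): 2.0})
    h_sd: float = 0.5
    n_rounds: int = 4
    naive_diversity_train: int = 20000
    naive_diversity_test: int = 12000
    max_positives: int = 1200
    # cells captured per round ~ 8x the naive diversity, the platform's
    # stated capture ratio
    cells_per_naive: int = 8
    sequencing_depth: int = 100_000
    alpha: float = 0.05
    n_test: int = 2000
    embed_dim: int = 32
    channels: tuple[int, ...] = (6, 12, 24)
    epochs: int = 25
    batch_size: int = 64
    lr: float = 1e-3
    standardize_input: bool = True
    include_round_trend: bool = False


@dataclass
class TransferResult:
    auc: float
    ap: float
    per_bin: pd.DataFrame
    report: EvalReport
    n_train: int
    n_test: int
    seed: int


def _screen_test_set(
    tables, rounds, alpha: float, n_test: int, seed: int
) -> pd.DataFrame:
    """Positive/negative test pairs from an expanded-alphabet screen:
    positives = enrichment-filtered pairs of the late rounds, negatives =
    naive pairs absent from those rounds, subsampled to about n_test
    balanced examples."""
    enriched = filter_pairs(tables, rounds, alpha=alpha)
    if enriched.df.empty:
        raise RuntimeError("no enriched pairs in the test screen")
    present = set(zip(*(pool_counts(tables, rounds)[c] for c in ("seq_a", "seq_b"))))
    naive = tables[0].df
    neg_mask = [(a, b) not in present
                for a, b in zip(naive["seq_a"], naive["seq_b"])]
    negatives = naive[neg_mask]
    rng = np.random.default_rng(seed)
    half = n_test // 2
    n_pos = min(half, len(enriched.df))
    n_neg = min(n_test - n_pos, len(negatives))
    pos_idx = np.sort(rng.choice(len(enriched.df), size=n_pos, replace=False))
    neg_idx = np.sort(rng.choice(len(negatives), size=n_neg, replace=False))
    pos = enriched.df.iloc[pos_idx][["seq_a", "seq_b"]].assign(cls="positive")
    neg = negatives.iloc[neg_idx][["seq_a", "seq_b"]].assign(cls="negative")
    return pd.concat([pos, neg], ignore_index=True)


def transfer_experiment(
    seed: int,
    settings: TransferSettings | None = None,
) -> TransferResult:
    """Run one seed of the restricted-to-expanded transfer experiment."""
    st = settings or TransferSettings()
    design_train = restricted_design()
    design_test = ll2_design()
    ua, ub = union_alphabets(design_train, design_test)
    landscape = build_landscape(
        design_test, st.planted, seed=seed, h_sd=st.h_sd,
        alphabets_A=ua, alphabets_B=ub,
    )

    cfg_train = SelectionConfig(
        n_rounds=st.n_rounds, naive_diversity=st.naive_diversity_train,
        cells_per_round=st.cells_per_naive * st.naive_diversity_train,
        sequencing_depth=st.sequencing_depth, seed=seed * 2 + 1,
    )
    cfg_test = SelectionConfig(
        n_rounds=st.n_rounds, naive_diversity=st.naive_diversity_test,
        cells_per_round=st.cells_per_naive * st.naive_diversity_test,
        sequencing_depth=st.sequencing_depth, seed=seed * 2 + 2,
    )
    train_tables = simulate_screen(design_train, landscape, cfg_train)
    test_tables = simulate_screen(design_test, landscape, cfg_test)
    late = [f"round{st.n_rounds - 1}", f"round{st.n_rounds}"]

    enriched = filter_pairs(train_tables, late, alpha=st.alpha)
    dataset = assemble_dataset(
        train_tables[0], enriched,
        [t for t in train_tables if t.round_label in late],
        seed=seed,
        max_positives=st.max_positives,
    )
    embedder = PhysicochemicalEmbedder(dim=st.embed_dim)
    config = ModelConfig(
        channels=st.channels, epochs=st.epochs, batch_size=st.batch_size,
        lr=st.lr, seed=seed, standardize_input=st.standardize_input,
    )
    bundle = train_model(dataset, embedder, config, design_train)

    test_df = _screen_test_set(test_tables, late, st.alpha, st.n_test, seed + 1000)
    train_alpha = (
        "".join(sorted(set("".join(design_train.alphabets_A)))),
        "".join(sorted(set("".join(design_train.alphabets_B)))),
    )
    report = evaluate(
        bundle, test_df, embedder, design_test,
        training_alphabets=train_alpha,
        per_round_tables=test_tables if st.include_round_trend else None,
    )
    return TransferResult(
        auc=report.auc, ap=report.ap, per_bin=report.per_bin, report=report,
        n_train=len(dataset.df), n_test=len(test_df), seed=seed,
    )
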