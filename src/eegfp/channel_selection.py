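"""Orthogonal forward search over EEG channels.

Greedy forward selection: start from an empty selected set C and a search
space E; at each step score every remaining candidate on inputs built from
C + [candidate] — with each recording's channels Gram-Schmidt orthogonalized
in selection order when the flag is set — and append the arg-max candidate.
Ties break toward the candidate earliest in sorted label order, so runs are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .errors import ScorerError, SelectionError
from .fingerprint_model import (
    ClassifierConfig,
    build_classifier,
    train_classifier,
)
from .preprocess import WindowParams, build_input_array
from .signal_io import EegRecording, normalize_label

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "forward_select", "score_channel_set", "make_scorer"]


@dataclass
class SelectionResult:
    """Outcome of the forward search."""

    selected: list[str]
    search_space_remaining: list[str]
    step_scores: list[float]
    step_tables: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert len(self.selected) == len(set(self.selected))
        assert not set(self.selected) & set(self.search_space_remaining)
        assert len(self.step_scores) == len(self.selected)

    def to_report(self, orthogonalized: bool = True) -> list[dict]:
        """Rows mirroring the step / previously-selected / next-channel /
        accuracy layout of the search log."""
        rows = []
        for i, (ch, score) in enumerate(zip(self.selected, self.step_scores)):
            rows.append({
                "step": i + 1,
                "previously_selected": self.selected[:i],
                "orthogonalized": bool(orthogonalized and i > 0),
                "next_channel": ch,
                "accuracy": score,
                "candidates": self.step_tables[i] if i < len(self.step_tables) else {},
            })
        return rows


def forward_select(
    cohort: list[EegRecording],
    search_space,
    max_channels: int,
    scorer,
    orthogonalize_flag: bool = True,
    seed: int = 0,
) -> SelectionResult:
    """Greedy (orthogonal) forward channel selection.

    ``scorer(channels, orthogonalize_flag, seed) -> accuracy fraction`` must
    be deterministic given the seed; see :func:`make_scorer`.  A candidate
    whose scorer raises is skipped with a warning; if every candidate of a
    step fails, a :class:`SelectionError` is raised.  ``max_channels=0`` (or
    an empty search space) returns an empty result.
    """
    space = sorted(dict.fromkeys(normalize_label(c) for c in search_space))
    if max_channels > len(space):
        raise SelectionError(
            f"max_channels={max_channels} exceeds search space of {len(space)}"
        )
    for rec in cohort:
        missing = [c for c in space if c not in rec.channel_names]
        if missing:
            raise SelectionError(
                f"recording {rec.subject_id} lacks channels {missing}"
            )

    selected: list[str] = []
    scores: list[float] = []
    tables: list[dict[str, float]] = []
    remaining = list(space)
    for step in range(max_channels):
        table: dict[str, float] = {}
        for cand in remaining:  # sorted order = deterministic tie-break
            try:
                table[cand] = float(
                    scorer(selected + [cand], orthogonalize_flag, seed)
                )
            except Exception as exc:  # scorer failure skips the candidate
                logger.warning(
                    "step %d: scorer failed on candidate %s: %s",
                    step + 1, cand, exc,
                )
        if not table:
            raise SelectionError(
                f"every candidate failed at step {step + 1}"
            )
        best = max(table, key=table.__getitem__)  # first max in sorted order
        selected.append(best)
        scores.append(table[best])
        tables.append(table)
        remaining.remove(best)
        logger.info(
            "step %d: selected %s (accuracy %.4f)", step + 1, best, table[best]
        )
    return SelectionResult(
        selected=selected,
        search_space_remaining=remaining,
        step_scores=scores,
        step_tables=tables,
    )


def score_channel_set(
    cohort: list[EegRecording],
    channels,
    params: WindowParams,
    model_config: ClassifierConfig,
    split_seed: int = 0,
    orthogonalize_flag: bool = False,
    test_fraction: float = 0.25,
) -> float:
    """Test accuracy of the CNN trained on inputs from ``channels``.

    Builds all augmented inputs across the cohort (orthogonalizing within
    each recording in channel order when requested), makes a seeded
    stratified train/test split, trains the classifier from scratch, and
    returns accuracy on the held-out inputs, in [0, 1].
    """
    channels = [normalize_label(c) for c in channels]
    subjects = sorted({rec.subject_id for rec in cohort})
    if len(subjects) < 2:
        raise ScorerError("scoring requires a cohort with >= 2 subjects")
    label_of = {sid: i for i, sid in enumerate(subjects)}

    xs, ys = [], []
    for rec in cohort:
        x, _ = build_input_array(
            rec, channels, params, orthogonalize_flag=orthogonalize_flag
        )
        xs.append(x)
        ys.append(np.full(x.shape[0], label_of[rec.subject_id]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=split_seed, stratify=y
    )
    config = ClassifierConfig(**{
        **model_config.to_dict(),
        "n_classes": len(subjects),
        "conv_blocks": model_config.conv_blocks,
        "pool_size": model_config.pool_size,
        "stride": model_config.stride,
        "seed": split_seed,
    })
    model = build_classifier(config, x.shape[1:])
    train_classifier(model, x_tr, y_tr, config)
    pred = model.predict_proba(x_te).argmax(axis=1)
    return float((pred == y_te).mean())


def make_scorer(cohort, params: WindowParams, model_config: ClassifierConfig,
                test_fraction: float = 0.25):
    """Bind cohort/params/config into the scorer signature
    ``(channels, orthogonalize_flag, seed) -> accuracy``."""

    def scorer(channels, orthogonalize_flag, seed):
        return score_channel_set(
            cohort, channels, params, model_config,
            split_seed=seed, orthogonalize_flag=orthogonalize_flag,
            test_fraction=test_fraction,
        )

    return scorer
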