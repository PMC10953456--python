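"""HyperBand search over spiral-trajectory parameters.

Each candidate is a full trajectory+network pair: the training pairs are
regenerated with the candidate's own trajectory, a denoiser is trained on
them, and validation SSIM drives successive halving.  Brackets follow the
canonical schedule: ``s_max = floor(log_eta R)`` brackets indexed
``s = s_max..0``; bracket s starts ``n = ceil((s_max+1) * eta^s / (s+1))``
configurations at ``max(1, floor(R * eta^-s))`` epochs, keeps the top
``floor(n/eta)`` each round and multiplies the budget by eta (capped at R).
Epochs are charged incrementally: a surviving trial resumes from its
checkpoint instead of restarting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DenoiserState
from .trajectory import PARAM_RANGES, SpiralParams

__all__ = [
    "HyperBandConfig",
    "TrialRecord",
    "sample_config",
    "hyperband_schedule",
    "run_search",
    "retrain_final",
    "split_dataset",
]


@dataclass(frozen=True)
class HyperBandConfig:
    """Search budget and data-split settings.

    ``max_resource`` is the epoch cap R per configuration; ``eta`` the
    discard ratio between rounds.  ``search_subset`` is the fraction of the
    corpus used during the search, split ``split_search`` (train, val);
    ``split_final`` is the (train, val, test) split for the final retrain.
    """

    max_resource: int = 150
    eta: int = 5
    seed: int = 0
    search_subset: float = 0.40
    split_search: tuple[float, float] = (0.30, 0.10)
    split_final: tuple[float, float, float] = (0.75, 0.10, 0.15)

    def __post_init__(self) -> None:
        if self.max_resource < 1:
            raise ValueError("max_resource must be >= 1")
        if self.eta < 2:
            raise ValueError("eta must be >= 2")
        if sum(self.split_search) > 1.0 + 1e-9 or sum(self.split_final) > 1.0 + 1e-9:
            raise ValueError("split fractions must sum to <= 1")


@dataclass
class TrialRecord:
    """One sampled configuration and its training outcome."""

    trial_id: int
    params: SpiralParams
    bracket: int
    epochs_used: int = 0
    best_val_ssim: float = -np.inf
    state: DenoiserState | None = None
    failed: bool = False
    error: str | None = None
    rounds: list = field(default_factory=list)
    _data: tuple | None = field(default=None, repr=False)

    def to_json(self) -> dict:
        p = self.params
        return {
            "trial_id": self.trial_id,
            "bracket": self.bracket,
            "epochs_used": self.epochs_used,
            "best_val_ssim": None if np.isinf(self.best_val_ssim) else self.best_val_ssim,
            "failed": self.failed,
            "error": self.error,
            "rounds": self.rounds,
            "params": {
                "r_inner": p.r_inner,
                "a_inner": p.a_inner,
                "r_outer": p.r_outer,
                "density_ratio": p.density_ratio,
                "transition": p.transition,
                "ordering": p.ordering,
                "tr_ms": p.tr_ms,
            },
        }


def sample_config(rng: np.random.Generator, t_acq_ms: float = 55.0) -> SpiralParams:
    """Draw one spiral configuration uniformly from the search space."""
    r_inner = rng.uniform(*PARAM_RANGES["r_inner"])
    a_inner = rng.uniform(*PARAM_RANGES["a_inner"])
    r_outer = rng.uniform(r_inner, 1.0 - r_inner)
    density_ratio = rng.uniform(*PARAM_RANGES["density_ratio"])
    transition = ("linear", "hanning", "quadratic")[rng.integers(3)]
    ordering = ("linear", "tiny_golden")[rng.integers(2)]
    tr_ms = rng.uniform(*PARAM_RANGES["tr_ms"])
    return SpiralParams(
        r_inner=r_inner,
        a_inner=a_inner,
        r_outer=r_outer,
        density_ratio=density_ratio,
        transition=transition,
        ordering=ordering,
        tr_ms=tr_ms,
        t_acq_ms=t_acq_ms,
    )


def hyperband_schedule(max_resource: int, eta: int) -> list[list[tuple[int, int]]]:
    """Bracket plan: list of brackets, each a list of (n_configs, epoch budget).

    Budgets are cumulative per trial; the incremental charge for a promoted
    trial is the difference from the previous round.
    """
    if max_resource < 1 or eta < 2:
        raise ValueError("need max_resource >= 1 and eta >= 2")
    s_max = int(np.floor(np.log(max_resource) / np.log(eta)))
    brackets = []
    for s in range(s_max, -1, -1):
        n = int(np.ceil((s_max + 1) * eta**s / (s + 1)))
        rounds = []
        for i in range(s + 1):
            n_i = max(1, int(np.floor(n * eta**-i)))
            r_i = min(max_resource, max(1, int(np.floor(max_resource * eta ** (i - s)))))
            rounds.append((n_i, r_i))
        brackets.append(rounds)
    return brackets


def total_scheduled_epochs(max_resource: int, eta: int) -> int:
    """Total incremental epochs charged by the schedule (continuation)."""
    total = 0
    for rounds in hyperband_schedule(max_resource, eta):
        prev = 0
        for n_i, r_i in rounds:
            total += n_i * (r_i - prev)
            prev = r_i
    return total


def run_search(
    dataset,
    config: HyperBandConfig,
    make_trial_data,
    train_trial,
    sample=sample_config,
) -> tuple[TrialRecord, list[TrialRecord]]:
    """Run the full HyperBand search; returns (best trial, all trials).

    ``make_trial_data(params, train_items, val_items)`` builds the
    trajectory-specific (train_set, val_set) example lists for a trial;
    ``train_trial(record, train_set, val_set, extra_epochs)`` trains or
    resumes the trial's network and returns its best validation SSIM so far.
    Promotion is strictly by validation SSIM (ties broken by lower trial id);
    failing trials are logged and excluded from promotion.
    """
    rng = np.random.default_rng(config.seed)
    train_items, val_items = split_dataset(
        dataset,
        fractions=config.split_search,
        subset=config.search_subset,
        seed=config.seed,
    )[:2]
    trials: list[TrialRecord] = []
    next_id = 0
    for b, rounds in enumerate(hyperband_schedule(config.max_resource, config.eta)):
        n0 = rounds[0][0]
        bracket_trials = []
        for _ in range(n0):
            rec = TrialRecord(trial_id=next_id, params=sample(rng), bracket=b)
            next_id += 1
            trials.append(rec)
            bracket_trials.append(rec)
        alive = list(bracket_trials)
        for rnd, (n_i, r_i) in enumerate(rounds):
            # Promote the top n_i by validation SSIM (ties: lower trial id).
            alive = alive[:n_i]
            for rec in alive:
                extra = r_i - rec.epochs_used
                if extra <= 0 or rec.failed:
                    continue
                try:
                    if rec._data is None:
                        rec._data = make_trial_data(rec.params, train_items, val_items)
                    tr, va = rec._data
                    rec.best_val_ssim = train_trial(rec, tr, va, extra)
                    rec.epochs_used = r_i
                    rec.rounds.append({"round": rnd, "epochs": r_i,
                                       "val_ssim": rec.best_val_ssim})
                except Exception as exc:  # noqa: BLE001 - robustness of long searches
                    rec.failed = True
                    rec.error = f"{type(exc).__name__}: {exc}"
            survivors = [r for r in alive if not r.failed]
            survivors.sort(key=lambda r: (-r.best_val_ssim, r.trial_id))
            alive = survivors
    ok = [r for r in trials if not r.failed and np.isfinite(r.best_val_ssim)]
    if not ok:
        raise RuntimeError("all trials failed")
    best = min(ok, key=lambda r: (-r.best_val_ssim, r.trial_id))
    return best, trials


def retrain_final(
    params: SpiralParams,
    dataset,
    epochs: int,
    config: HyperBandConfig,
    make_trial_data,
    train_final,
):
    """Retrain from scratch on the full corpus with the final three-way split.

    ``train_final(params, train_set, val_set, epochs)`` must return the
    trained state.  Returns (state, test_items).
    """
    train_items, val_items, test_items = split_dataset(
        dataset, fractions=config.split_final, subset=1.0, seed=config.seed
    )
    tr, va = make_trial_data(params, train_items, val_items)
    state = train_final(params, tr, va, epochs)
    return state, test_items


def split_dataset(dataset, fractions, subset: float = 1.0, seed: int = 0):
    """Shuffle and partition a list into len(fractions) parts (plus remainder).

    ``subset`` first restricts to a random fraction of the corpus, as done
    when searching on a reduced portion of the data.
    """
    items = list(dataset)
    rng = np.random.default_rng([seed, len(items)])
    order = rng.permutation(len(items))
    if subset < 1.0:
        # Keep at least one item per requested part.
        keep = max(len(fractions), int(round(subset * len(items))))
        order = order[: min(keep, len(items))]
    n = len(order)
    counts = []
    for i, f in enumerate(fractions):
        if i == len(fractions) - 1 and abs(sum(fractions) - 1.0) < 1e-9:
            c = n - sum(counts)  # exact partition when fractions cover 1
        else:
            # Fractions refer to the full corpus (30/10 of the whole is
            # 75/25 of a 40% subset).
            c = int(round(f * len(items)))
        remaining_parts = len(fractions) - 1 - i
        c = max(1, min(c, n - sum(counts) - remaining_parts))
        counts.append(c)
    parts = []
    start = 0
    for c in counts:
        parts.append([items[j] for j in order[start: start + c]])
        start += c
    return tuple(parts)
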