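"""Metropolis Monte Carlo sequence evolution.

Starting from a random admissible pair, the engine perturbs the sequences
with three move types -- intrachain residue mutation, intrachain residue
exchange, and interchain residue exchange -- scores each trial on the fixed
fibril scaffold, and accepts moves with the Metropolis criterion on the
change in Gamma: score-lowering moves are always accepted, score-raising
moves with probability exp(-dGamma/T).  Every visited state satisfies the
sequence constraints by construction of the moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MoveError
from .scoring import (AggregationParams, EnergyParams, ScoreBreakdown,
                      score_pair)
from .scaffold_model import FibrilScaffold, build_scaffold
from .sequence_space import (CompositionConstraint, PeptidePair,
                             ResidueClassTable, SequencePattern, random_pair,
                             validate_pair)

__all__ = [
    "MOVE_TYPES",
    "MCConfig",
    "MCState",
    "RunResult",
    "propose_move",
    "metropolis_accept",
    "run_design",
]

MOVE_TYPES = ("mutation", "intra_exchange", "inter_exchange")


@dataclass
class MCConfig:
    """Run parameters of the sequence-evolution engine."""

    n_steps: int = 2000
    effective_temperature: float = 1.0     # kcal/mol; Metropolis scale
    move_probabilities: tuple = (0.5, 0.25, 0.25)
    rng_seed: int = 0
    lambda_weight: float = 3.0
    report_stride: int = 10
    anneal_final_temperature: float | None = None  # linear schedule if set
    n_best: int = 6
    max_retries: int = 100

    def __post_init__(self):
        probs = tuple(float(p) for p in self.move_probabilities)
        if len(probs) != 3 or min(probs) < 0 or abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigurationError(
                "move_probabilities must be 3 nonnegative values summing to 1")
        self.move_probabilities = probs
        if self.effective_temperature <= 0:
            raise ConfigurationError("effective_temperature must be positive")
        if self.anneal_final_temperature is not None \
                and self.anneal_final_temperature <= 0:
            raise ConfigurationError("anneal_final_temperature must be positive")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.report_stride < 1:
            raise ConfigurationError("report_stride must be >= 1")

    def temperature_at(self, step: int) -> float:
        """Temperature for a 1-based step under the (optional) linear schedule."""
        if self.anneal_final_temperature is None or self.n_steps == 1:
            return self.effective_temperature
        frac = (step - 1) / (self.n_steps - 1)
        return (self.effective_temperature
                + frac * (self.anneal_final_temperature
                          - self.effective_temperature))


@dataclass
class MCState:
    current_pair: PeptidePair
    current_score: ScoreBreakdown
    best_pair: PeptidePair
    best_score: ScoreBreakdown
    step_index: int = 0
    acceptance_counts: dict = field(default_factory=lambda: {
        m: {"proposed": 0, "accepted": 0} for m in MOVE_TYPES})


@dataclass
class RunResult:
    trace: pd.DataFrame            # step, gamma, dg, p_agg, move_type, accepted
    best_designs: list             # [(gamma, step, PeptidePair)] ascending
    state: MCState


def _mutate_site(seq: list, i: int, pool: list, rng) -> bool:
    choices = [aa for aa in pool if aa != seq[i]]
    if not choices:
        return False
    seq[i] = choices[rng.integers(len(choices))]
    return True


def propose_move(pair: PeptidePair, move_type: str,
                 pattern: SequencePattern | None = None,
                 comp: CompositionConstraint | None = None,
                 table: ResidueClassTable | None = None,
                 rng: np.random.Generator | None = None,
                 max_retries: int = 100) -> PeptidePair:
    """Generate one constraint-preserving trial pair.

    mutation        -- one site's residue replaced by a different residue of
                       the same class (charged sites keep their sign);
    intra_exchange  -- two same-chain residues on sites of the same pattern
                       class (two P sites or two H sites) swapped;
    inter_exchange  -- residues at one A site and one B site swapped, legal
                       only for classes valid on both chains (hydrophobic or
                       polar, never charged).
    """
    pattern = pattern or SequencePattern()
    comp = comp or CompositionConstraint()
    table = table or ResidueClassTable()
    rng = rng if rng is not None else np.random.default_rng()
    if move_type not in MOVE_TYPES:
        raise ConfigurationError(f"unknown move type {move_type!r}")
    h_sites = pattern.h_sites
    p_sites = pattern.p_sites
    polar = table.polar_set

    for _ in range(max_retries):
        a = list(pair.seq_a)
        b = list(pair.seq_b)
        chains = {"A": a, "B": b}
        if move_type == "mutation":
            label = ("A", "B")[rng.integers(2)]
            seq = chains[label]
            i = int(rng.integers(len(seq)))
            if i in h_sites:
                pool = sorted(table.hydrophobic_set)
            elif seq[i] in polar:
                pool = sorted(polar)
            else:
                pool = sorted(table.positive_set if label == "A"
                              else table.negative_set)
            if not _mutate_site(seq, i, pool, rng):
                continue
        elif move_type == "intra_exchange":
            label = ("A", "B")[rng.integers(2)]
            seq = chains[label]
            sites = h_sites if (rng.random() < 0.5 and len(h_sites) >= 2) \
                else p_sites
            if len(sites) < 2:
                continue
            i, j = rng.choice(len(sites), size=2, replace=False)
            i, j = sites[int(i)], sites[int(j)]
            if seq[i] == seq[j]:
                continue
            seq[i], seq[j] = seq[j], seq[i]
        else:  # inter_exchange
            # Candidate site pairs where both residues are hydrophobic or
            # both are uncharged-polar (charged residues cannot cross chains).
            cands = [(i, j)
                     for i in range(len(a)) for j in range(len(b))
                     if ((i in h_sites and j in h_sites)
                         or (a[i] in polar and b[j] in polar))
                     and a[i] != b[j]]
            if not cands:
                continue
            i, j = cands[int(rng.integers(len(cands)))]
            a[i], b[j] = b[j], a[i]
        trial = PeptidePair("".join(a), "".join(b))
        if validate_pair(trial, pattern, comp, table).ok:
            return trial
    raise MoveError(
        f"no legal {move_type} move found in {max_retries} attempts")


def metropolis_accept(delta_gamma: float, temperature: float,
                      rng: np.random.Generator | None = None) -> bool:
    """Metropolis criterion: accept iff dGamma <= 0 or u < exp(-dGamma/T)."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    if delta_gamma <= 0:
        return True
    rng = rng if rng is not None else np.random.default_rng()
    return bool(rng.random() < np.exp(-delta_gamma / temperature))


def run_design(config: MCConfig | None = None,
               pattern: SequencePattern | None = None,
               comp: CompositionConstraint | None = None,
               table: ResidueClassTable | None = None,
               scaffold: FibrilScaffold | None = None,
               energy_params: EnergyParams | None = None,
               agg_params: AggregationParams | None = None,
               initial_pair: PeptidePair | None = None) -> RunResult:
    """Run one sequence-evolution trajectory; fully reproducible per seed."""
    config = config or MCConfig()
    pattern = pattern or SequencePattern()
    comp = comp or CompositionConstraint()
    table = table or ResidueClassTable()
    scaffold = scaffold or build_scaffold()
    energy_params = energy_params or EnergyParams()
    agg_params = agg_params or AggregationParams()
    rng = np.random.default_rng(config.rng_seed)

    def score(p: PeptidePair) -> ScoreBreakdown:
        return score_pair(p, scaffold, energy_params, agg_params,
                          config.lambda_weight, validate=False)

    current = initial_pair or random_pair(pattern=pattern, comp=comp,
                                          table=table, rng=rng)
    current_score = score(current)
    state = MCState(current_pair=current, current_score=current_score,
                    best_pair=current, best_score=current_score)
    # distinct best designs, keyed by sequences -> (gamma, step, pair)
    best_pool = {(current.seq_a, current.seq_b):
                 (current_score.gamma_score, 0, current)}
    records = []

    for step in range(1, config.n_steps + 1):
        move_idx = rng.choice(3, p=config.move_probabilities)
        move_type = MOVE_TYPES[int(move_idx)]
        state.acceptance_counts[move_type]["proposed"] += 1
        trial = propose_move(state.current_pair, move_type, pattern, comp,
                             table, rng, config.max_retries)
        trial_score = score(trial)
        delta = trial_score.gamma_score - state.current_score.gamma_score
        accepted = metropolis_accept(delta, config.temperature_at(step), rng)
        if accepted:
            state.acceptance_counts[move_type]["accepted"] += 1
            state.current_pair = trial
            state.current_score = trial_score
            key = (trial.seq_a, trial.seq_b)
            gamma = trial_score.gamma_score
            if key not in best_pool or gamma < best_pool[key][0]:
                best_pool[key] = (gamma, step, trial)
            if len(best_pool) > 4 * config.n_best:
                best_pool = dict(sorted(best_pool.items(),
                                        key=lambda kv: kv[1][0])
                                 [:config.n_best])
            if gamma < state.best_score.gamma_score:
                state.best_pair = trial
                state.best_score = trial_score
        state.step_index = step
        if step % config.report_stride == 0:
            records.append({
                "step": step,
                "gamma": state.current_score.gamma_score,
                "dg": state.current_score.dg_binding,
                "p_agg": state.current_score.p_agg,
                "move_type": move_type,
                "accepted": accepted,
            })

    best = sorted(best_pool.values(), key=lambda t: t[0])[:config.n_best]
    trace = pd.DataFrame.from_records(
        records, columns=["step", "gamma", "dg", "p_agg", "move_type",
                          "accepted"])
    return RunResult(trace=trace, best_designs=best, state=state)
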