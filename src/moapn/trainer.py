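"""Training and evaluation loops for the five-agent objective-adjustment
policy.

One episode walks a case through repeated adjustment steps: every agent
picks an action for its ring objective (epsilon-greedy while training,
greedy at evaluation), all five objectives are updated, one optimization
pass re-solves the plan (warm-started from the previous weights), and each
agent is rewarded by the plan-score change.  Episodes stop at the step cap
(20 while training, 25 at evaluation) or as soon as PTV coverage drops
below 95% of prescription.

While training, each agent stores its transition with maximum priority in
its own Sum-Tree pool, samples a batch of 20, takes one Adam step on the
DDQN loss, and refreshes the sampled priorities with the new TD errors;
target networks are replaced by the evaluation networks every 80
adjustment steps.  Epsilon starts at 0.95 and decays multiplicatively by
0.95 per episode down to 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dvh_metrics import PlanState, agent_view, plan_metrics
from .dose_engine import InfluenceMatrix
from .init_objectives import initial_objectives
from .moapn_agent import (
    AgentEnsemble,
    Transition,
    apply_action,
    reward,
    train_step,
)
from .phantom import Case, RING_NAMES
from .plan_optim import ObjectiveSet, OptimConfig, optimize_plan
from .scoring import ScoringConfig, eva_score

__all__ = [
    "TrainingConfig",
    "EpisodeLog",
    "epsilon_at",
    "run_episode",
    "train",
    "evaluate",
    "normalized_metrics",
]


@dataclass
class TrainingConfig:
    """All knobs of the training/evaluation loops with their defaults."""

    gamma: float = 0.9
    learning_rate: float = 1e-3
    epsilon_start: float = 0.95
    epsilon_decay: float = 0.95
    epsilon_min: float = 0.1
    pool_capacity: int = 4096
    batch_size: int = 20
    target_sync_steps: int = 80
    max_steps_train: int = 20
    max_steps_eval: int = 25
    coverage_floor: float = 0.95  # fraction of the prescription dose
    priority_offset: float = 1e-2
    objective_floor_gy: float = 0.5
    #: plan-score changes below this are "unchanged" for the reward; set to
    #: one score point so surrogate-optimizer jitter does not masquerade as
    #: real plan-quality change
    eva_tol: float = 1.0
    n_episodes: int = 30
    prescription_gy: float = 50.0
    normalize_eval: bool = True
    optim: OptimConfig = field(default_factory=OptimConfig)

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if not 0 <= self.epsilon_min <= self.epsilon_start <= 1:
            raise ValueError("need 0 <= epsilon_min <= epsilon_start <= 1")
        for name in ("pool_capacity", "batch_size", "target_sync_steps",
                     "max_steps_train", "max_steps_eval", "n_episodes"):
            if getattr(self, name) < 1 and name != "n_episodes":
                raise ValueError(f"{name} must be a positive integer")


def epsilon_at(episode: int, config: TrainingConfig) -> float:
    """Exploration probability for an episode index (0-based):
    max(eps_min, eps_start * decay^episode)."""
    if episode < 0:
        raise ValueError("episode index must be >= 0")
    return max(
        config.epsilon_min,
        config.epsilon_start * config.epsilon_decay**episode,
    )


@dataclass
class EpisodeLog:
    """Per-step records of one episode plus its endpoints."""

    steps: list[dict]
    termination: str  # "max_steps" | "coverage_floor"
    cumulative_reward: float
    initial_plan: PlanState
    final_plan: PlanState
    #: last plan (possibly the initial one) whose PTV D95 met the coverage
    #: floor; equals final_plan unless the episode ended by breaching it
    final_covered_plan: PlanState | None = None
    case_seed: int = -1
    episode: int = -1
    epsilon: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _score_plan(plan: PlanState, scoring: ScoringConfig) -> PlanState:
    plan.eva_score = eva_score(plan, scoring)
    return plan


def run_episode(
    case: Case,
    influence: InfluenceMatrix,
    ensemble: AgentEnsemble,
    objectives_0: ObjectiveSet,
    config: TrainingConfig,
    mode: str = "train",
    rng: np.random.Generator | None = None,
    scoring: ScoringConfig | None = None,
    initial_plan: PlanState | None = None,
    episode: int = 0,
) -> EpisodeLog:
    """Run one adjustment episode on a case.

    ``mode='train'`` uses epsilon-greedy actions and updates the agents;
    ``mode='eval'`` is greedy and leaves them untouched.  Deterministic for
    a fixed ``rng`` state and ensemble.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    rng = rng if rng is not None else np.random.default_rng(0)
    scoring = scoring or ScoringConfig.from_ring_objectives(
        objectives_0.ring_objectives()
    )
    eps = epsilon_at(episode, config) if mode == "train" else 0.0
    dp = config.prescription_gy
    max_steps = config.max_steps_train if mode == "train" else config.max_steps_eval

    objectives = objectives_0.copy()
    if initial_plan is None:
        plan_prev = optimize_plan(influence, case, objectives, config.optim)
    else:
        plan_prev = initial_plan
    if plan_prev.eva_score is None:
        _score_plan(plan_prev, scoring)
    first_plan = plan_prev

    steps: list[dict] = []
    termination = "max_steps"
    cumulative = 0.0
    floor = config.coverage_floor * dp
    last_covered = plan_prev if plan_prev.metrics["ptv_d95"] >= floor else None
    for t in range(1, max_steps + 1):
        agent_states = {r: agent_view(plan_prev.dvh, r) for r in RING_NAMES}
        actions: dict[str, int] = {}
        for r in RING_NAMES:
            if mode == "train" and rng.uniform() < eps:
                actions[r] = int(rng.integers(4))
            else:
                q = ensemble.networks[r].q_eva.forward(agent_states[r])[0]
                actions[r] = int(np.argmax(q))
        for r in RING_NAMES:
            entry = objectives.entry_for(r, "geud_upper")
            entry.dose_gy = apply_action(
                entry.dose_gy, actions[r], floor_gy=config.objective_floor_gy
            )

        plan_next = optimize_plan(
            influence, case, objectives, config.optim, warm_start=plan_prev.weights
        )
        plan_next.step_index = t
        _score_plan(plan_next, scoring)

        rewards: dict[str, float] = {}
        terminal = False
        for r in RING_NAMES:
            r_k, term_k = reward(
                plan_prev, plan_next, actions[r], r, dp=dp, eva_tol=config.eva_tol
            )
            rewards[r] = r_k
            terminal = terminal or term_k

        steps.append(
            {
                "step": t,
                "eva": plan_next.eva_score,
                "ptv_d95": plan_next.metrics["ptv_d95"],
                "objective_value": plan_next.objective_value,
                "mean_reward": float(np.mean(list(rewards.values()))),
                **{f"action_{r}": actions[r] for r in RING_NAMES},
                **{f"reward_{r}": rewards[r] for r in RING_NAMES},
                **{f"objective_{r}": plan_next.ring_objectives[r] for r in RING_NAMES},
                **{f"geud_{r}": plan_next.ring_geud[r] for r in RING_NAMES},
            }
        )
        cumulative += float(np.mean(list(rewards.values())))

        if mode == "train":
            next_states = {r: agent_view(plan_next.dvh, r) for r in RING_NAMES}
            ensemble.train_steps += 1
            for r in RING_NAMES:
                pool = ensemble.pools[r]
                pool.add(
                    pool.max_priority,
                    Transition(
                        state=agent_states[r],
                        action=actions[r],
                        reward=rewards[r],
                        next_state=next_states[r],
                        terminal=terminal,
                    ),
                )
                batch, leaves = pool.sample(config.batch_size, rng)
                _, td = train_step(
                    batch,
                    ensemble.networks[r],
                    gamma=config.gamma,
                    lr=config.learning_rate,
                )
                for leaf, err in zip(leaves, td):
                    pool.update(leaf, abs(float(err)) + config.priority_offset)
            if ensemble.train_steps % config.target_sync_steps == 0:
                ensemble.sync_targets()

        plan_prev = plan_next
        if plan_next.metrics["ptv_d95"] >= floor:
            last_covered = plan_next
        if terminal:
            termination = "coverage_floor"
            break

    return EpisodeLog(
        steps=steps,
        termination=termination,
        cumulative_reward=cumulative,
        initial_plan=first_plan,
        final_plan=plan_prev,
        final_covered_plan=last_covered,
        case_seed=case.seed,
        episode=episode,
        epsilon=eps,
    )


def train(
    cases: list[Case],
    influences: list[InfluenceMatrix],
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> tuple[AgentEnsemble, pd.DataFrame, list[EpisodeLog]]:
    """Train the ensemble over a case roster.

    Episodes cycle through the cases; every episode restarts from the
    case's patient-specific initial objectives.  Returns the trained
    ensemble, a one-row-per-episode training curve, and the episode logs.
    """
    if not cases:
        raise ValueError("need at least one training case")
    config = config or TrainingConfig()
    ss = np.random.SeedSequence(seed)
    ensemble_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    ensemble = AgentEnsemble.create(ensemble_seed, config.pool_capacity)
    episode_seeds = ss.spawn(max(config.n_episodes, 1))

    # per-case initial objectives / scoring / step-0 plan, fixed across episodes
    case_setup = []
    for case, infl in zip(cases, influences):
        objectives_0, _ = initial_objectives(
            case, prescription_gy=config.prescription_gy
        )
        scoring = ScoringConfig.from_ring_objectives(objectives_0.ring_objectives())
        plan0 = optimize_plan(infl, case, objectives_0, config.optim)
        _score_plan(plan0, scoring)
        case_setup.append((objectives_0, scoring, plan0))

    rows = []
    logs: list[EpisodeLog] = []
    for ep in range(config.n_episodes):
        i = ep % len(cases)
        objectives_0, scoring, plan0 = case_setup[i]
        rng = np.random.default_rng(episode_seeds[ep])
        log = run_episode(
            cases[i],
            influences[i],
            ensemble,
            objectives_0,
            config,
            mode="train",
            rng=rng,
            scoring=scoring,
            initial_plan=plan0,
            episode=ep,
        )
        logs.append(log)
        rows.append(
            {
                "episode": ep,
                "case_seed": cases[i].seed,
                "epsilon": log.epsilon,
                "n_steps": len(log.steps),
                "cumulative_reward": log.cumulative_reward,
                "termination": log.termination,
                "initial_eva": log.initial_plan.eva_score,
                "final_eva": log.final_plan.eva_score,
            }
        )
    return ensemble, pd.DataFrame(rows), logs


def normalized_metrics(
    plan: PlanState, case: Case, dp: float
) -> dict[str, float]:
    """Plan metrics after rescaling dose so the prescription covers 95% of
    the PTV (D95 = Dp) — the clinical reporting normalization.  Used for
    evaluation reports only, never for the RL state."""
    d95 = plan.metrics["ptv_d95"]
    if d95 <= 0:
        raise ValueError("cannot normalize a plan with zero PTV D95")
    return plan_metrics(plan.dose * (dp / d95), case, dp=dp)


def evaluate(
    cases: list[Case],
    influences: list[InfluenceMatrix],
    ensemble: AgentEnsemble,
    config: TrainingConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Greedy-policy evaluation over a cohort.

    For each case: build the initial plan from the patient-specific
    objectives, run one greedy episode (<= 25 steps), and compare final vs
    initial plans.  If the episode ended by breaching the coverage floor,
    the last plan that still covered the target is reported as final.
    Cohort-level paired Wilcoxon signed-rank tests compare final vs initial
    for the plan score and each reported metric.
    """
    if not cases:
        raise ValueError("empty evaluation cohort")
    config = config or TrainingConfig()
    dp = config.prescription_gy
    report_keys = (
        "chest_wall_dmax",
        "spinal_cord_dmax",
        "heart_dmax",
        "lung_v5",
        "esophagus_dmax",
        "bronchus_dmax",
        "d2cm_dmax",
    )
    rows = []
    for case, infl in zip(cases, influences):
        objectives_0, _ = initial_objectives(case, prescription_gy=dp)
        scoring = ScoringConfig.from_ring_objectives(objectives_0.ring_objectives())
        log = run_episode(
            case, infl, ensemble, objectives_0, config, mode="eval",
            scoring=scoring,
        )
        # a clinic would not accept a non-covering plan: report the last
        # plan along the trajectory that still met the coverage floor
        final = log.final_covered_plan or log.initial_plan
        if config.normalize_eval:
            init_m = normalized_metrics(log.initial_plan, case, dp)
            final_m = normalized_metrics(final, case, dp)
            init_eva = eva_score(init_m, scoring)
            final_eva = eva_score(final_m, scoring)
        else:
            init_m = log.initial_plan.metrics
            final_m = final.metrics
            init_eva = log.initial_plan.eva_score
            final_eva = final.eva_score
        row = {
            "case_seed": case.seed,
            "n_steps": len(log.steps),
            "termination": log.termination,
            "initial_eva": init_eva,
            "final_eva": final_eva,
        }
        for k in report_keys:
            row[f"initial_{k}"] = init_m[k]
            row[f"final_{k}"] = final_m[k]
        rows.append(row)
    report = pd.DataFrame(rows)

    def _wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
        diff = np.asarray(a) - np.asarray(b)
        if np.allclose(diff, 0):
            return float("nan")
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)

    summary = {
        "n_cases": len(report),
        "mean_steps": float(report["n_steps"].mean()),
        "improved_fraction": float(
            (report["final_eva"] >= report["initial_eva"]).mean()
        ),
        "p_eva": _wilcoxon(report["final_eva"], report["initial_eva"]),
    }
    for k in report_keys:
        summary[f"p_{k}"] = _wilcoxon(report[f"final_{k}"], report[f"initial_{k}"])
        denom = report[f"initial_{k}"].replace(0, np.nan)
        summary[f"mean_rel_change_{k}"] = float(
            ((report[f"final_{k}"] - report[f"initial_{k}"]) / denom).mean()
        )
    return report, summary
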