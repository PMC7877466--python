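"""Go/No-go reaction-time task generator.

Each subject completes 250 trials per hand both before and after the
neurofeedback session. A trial shows a warning cue for one of five
durations (100-500 ms, balanced), then a go (respond) or no-go (inhibit)
target for up to 1000 ms. Go reaction times are drawn from a shifted
log-normal around a configurable per-(hand, session) mean, which lets a
study configuration encode a post-training speed-up in a chosen cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HANDS = ("left", "right")
SESSIONS = ("pre", "post")
CUE_DURATIONS_MS = (100, 200, 300, 400, 500)
N_TRIALS = 250
TARGET_MS = 1000.0  # target display limit; slower responses are omissions

RT_SHIFT_MS = 200.0
RT_LOGNORM_SD = 0.4


def simulate_gonogo(
    effect_ms: dict[tuple[str, str], float],
    seed: int,
    n_trials: int = N_TRIALS,
    go_fraction: float = 0.8,
    p_omission: float = 0.03,
    p_commission: float = 0.05,
) -> pd.DataFrame:
    """Simulate one subject's full Go/No-go dataset (both hands x pre/post).

    Parameters
    ----------
    effect_ms
        Mean go reaction time (ms) for each of the four (hand, session)
        cells; all four must be present.
    seed
        Seeds trial order, RTs, and lapses.
    n_trials
        Trials per hand per session (250 in the study design).
    go_fraction
        Proportion of go trials; cue durations are balanced by design.
    p_omission, p_commission
        Probability of missing a go trial / responding on a no-go trial.
    """
    for hand in HANDS:
        for session in SESSIONS:
            if (hand, session) not in effect_ms:
                raise ValueError(f"effect_ms missing cell {(hand, session)}")
    rng = np.random.default_rng(seed)
    n_go = int(round(n_trials * go_fraction))
    rows = []
    for session in SESSIONS:
        for hand in HANDS:
            mean_rt = float(effect_ms[(hand, session)])
            if mean_rt <= RT_SHIFT_MS:
                raise ValueError(f"mean RT must exceed the {RT_SHIFT_MS} ms shift")
            # balanced composition: trial types and cue durations fixed by
            # design, order shuffled
            types = np.array(["go"] * n_go + ["nogo"] * (n_trials - n_go))
            cues = np.tile(CUE_DURATIONS_MS, n_trials // len(CUE_DURATIONS_MS) + 1)[:n_trials]
            order = rng.permutation(n_trials)
            types, cues = types[order], np.sort(cues)[rng.permutation(n_trials)]

            mu = np.log(mean_rt - RT_SHIFT_MS) - RT_LOGNORM_SD**2 / 2.0
            rts = RT_SHIFT_MS + rng.lognormal(mu, RT_LOGNORM_SD, size=n_trials)
            lapse = rng.random(n_trials)
            for i in range(n_trials):
                is_go = types[i] == "go"
                if is_go:
                    responded = lapse[i] >= p_omission and rts[i] <= TARGET_MS
                else:
                    responded = lapse[i] < p_commission
                rows.append(
                    {
                        "hand": hand,
                        "session": session,
                        "trial_index": i,
                        "cue_duration_ms": int(cues[i]),
                        "trial_type": types[i],
                        "response": bool(responded),
                        "rt_ms": float(rts[i]) if (is_go and responded) else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def mean_go_rt(
    table: pd.DataFrame, rt_min_ms: float = 100.0, rt_max_ms: float = 1000.0
) -> pd.DataFrame:
    """Per-(hand, session) mean go RT from responded go trials.

    No-go trials, omissions, and RTs outside [rt_min_ms, rt_max_ms] are
    excluded before averaging.
    """
    go = table[
        (table.trial_type == "go")
        & table.response
        & table.rt_ms.ge(rt_min_ms)
        & table.rt_ms.le(rt_max_ms)
    ]
    return go.groupby(["hand", "session"], as_index=False)["rt_ms"].mean()
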