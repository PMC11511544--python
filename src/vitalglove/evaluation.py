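"""False-alarm reduction bookkeeping.

The pipeline raises alert episodes on the raw signal and on each smoothed
variant of it.  Single-sample artifact spikes survive the raw signal but are
strongly attenuated by averaging, so the filtered variants raise fewer
episodes; the most aggressively smoothed variant (Gaussian, by the ranking
this system adopts) serves as the *reference*: raw episodes it confirms are
counted as true positives, the remainder as false alarms.

This is an internal-consistency convention, not clinical ground truth — the
report names its reference variant explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .alerts import AlertConfig, AlertEpisode, episodes, flag_series
from .session_io import PhaseSession
from .smoothing import FilterSpec, smooth_session

__all__ = ["EvaluationReport", "match_episodes", "compare_filters"]


@dataclass(frozen=True)
class EvaluationReport:
    """Episode counts per signal variant and the false-alarm tally.

    ``true_positive_pct`` is confirmed/raw × 100; when the raw signal raised
    no episodes at all it is 100 by convention (no alarms, hence no false
    alarms).
    """

    episode_counts: dict[str, int]
    reference_variant: str
    confirmed_count: int
    false_positive_count: int
    true_positive_pct: float
    matching_window_s: float

    def __post_init__(self) -> None:
        raw = self.episode_counts.get("raw", 0)
        if self.confirmed_count + self.false_positive_count != raw:
            raise ValueError("confirmed + false positives must equal raw count")
        if not 0.0 <= self.true_positive_pct <= 100.0:
            raise ValueError("true_positive_pct out of [0, 100]")

    def to_dict(self) -> dict:
        return {
            "episode_counts": dict(self.episode_counts),
            "reference_variant": self.reference_variant,
            "confirmed_count": self.confirmed_count,
            "false_positive_count": self.false_positive_count,
            "true_positive_pct": self.true_positive_pct,
            "matching_window_s": self.matching_window_s,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = ["alert episodes per signal variant:"]
        for name, count in self.episode_counts.items():
            marker = "  (reference)" if name == self.reference_variant else ""
            lines.append(f"  {name}: {count}{marker}")
        lines += [
            f"confirmed raw alerts: {self.confirmed_count}",
            f"false alarms: {self.false_positive_count}",
            f"true-positive rate: {self.true_positive_pct:.1f}%",
            f"matching window: {self.matching_window_s:g} s",
        ]
        return "\n".join(lines)


def match_episodes(
    candidate: Sequence[AlertEpisode],
    reference: Sequence[AlertEpisode],
    window_s: float,
    sample_period_s: float = 1.0,
) -> tuple[int, int]:
    """Count confirmed and false candidate episodes.

    A candidate is confirmed iff some reference episode lies within
    ``window_s`` of it (interval overlap after widening the reference by the
    window); each reference episode confirms at most one candidate, assigned
    greedily in order of candidate start time.  Returns
    ``(confirmed_count, false_positive_count)``.
    """
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    used = [False] * len(reference)
    confirmed = 0
    for cand in sorted(candidate, key=lambda e: e.start_index):
        c_lo = (cand.start_index - 1) * sample_period_s
        c_hi = (cand.end_index - 1) * sample_period_s
        for j, ref in enumerate(reference):
            if used[j]:
                continue
            r_lo = (ref.start_index - 1) * sample_period_s - window_s
            r_hi = (ref.end_index - 1) * sample_period_s + window_s
            if c_lo <= r_hi and r_lo <= c_hi:
                used[j] = True
                confirmed += 1
                break
    return confirmed, len(candidate) - confirmed


def compare_filters(
    session: PhaseSession,
    specs: Sequence[FilterSpec],
    config: AlertConfig,
    matching_window_s: float | None = None,
) -> EvaluationReport:
    """Run the alert engine on the raw session and each smoothed variant.

    The last spec in ``specs`` is the reference variant confirming raw
    episodes.  Episode grouping uses the config's refractory period as the
    merge gap; the matching window defaults to the same value.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    window = config.refractory_s if matching_window_s is None else matching_window_s

    def detect(sess: PhaseSession) -> list[AlertEpisode]:
        return episodes(
            flag_series(sess, config),
            sample_period_s=sess.sample_period_s,
            merge_gap_s=config.refractory_s,
            hr_bpm=sess.channel("hr_bpm"),
        )

    variants: dict[str, list[AlertEpisode]] = {"raw": detect(session)}
    for spec in specs:
        name = spec.label
        if name in variants:  # same filter twice: disambiguate
            name = f"{name}_{sum(k.startswith(spec.label) for k in variants)}"
        variants[name] = detect(smooth_session(session, spec))

    reference_name = list(variants)[-1]
    confirmed, false_pos = match_episodes(
        variants["raw"],
        variants[reference_name],
        window_s=window,
        sample_period_s=session.sample_period_s,
    )
    n_raw = len(variants["raw"])
    tp_pct = 100.0 if n_raw == 0 else 100.0 * confirmed / n_raw
    return EvaluationReport(
        episode_counts={k: len(v) for k, v in variants.items()},
        reference_variant=reference_name,
        confirmed_count=confirmed,
        false_positive_count=false_pos,
        true_positive_pct=tp_pct,
        matching_window_s=window,
    )
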