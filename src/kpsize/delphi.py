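"""Modified-Delphi consensus aggregation.

After the data-driven stages, stakeholders each submit a ballot with their
most-likely national estimate, lower and upper plausibility bounds, and a
low/medium/high density classification of each district. The consensus point
estimate and bounds are the component-wise medians of the valid ballots;
district density is coded low=1, medium=2, high=3 and averaged, with the mean
score mapped back to the nearest label. Additional rounds replace — never
average with — earlier rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import EstimationError, SchemaError

DENSITY_CODES = {"low": 1, "medium": 2, "high": 3}

__all__ = [
    "DENSITY_CODES",
    "DelphiBallot",
    "ConsensusResult",
    "consensus_estimate",
    "district_density",
    "density_label",
    "DelphiPanel",
    "DelphiResults",
]


@dataclass(frozen=True)
class DelphiBallot:
    """One stakeholder's national estimate and district classifications."""

    participant_id: str
    most_likely: float
    lower: float
    upper: float
    district_density: Mapping[str, str] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return (
            self.lower <= self.most_likely <= self.upper
            and all(v in DENSITY_CODES for v in self.district_density.values())
        )


@dataclass(frozen=True)
class ConsensusResult:
    """Median consensus for one round."""

    point: float
    lower: float
    upper: float
    round_number: int
    n_ballots: int
    rejected: tuple[str, ...] = ()

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise EstimationError(
                f"consensus not ordered: ({self.lower}, {self.point}, {self.upper})"
            )


def _split_valid(ballots: Sequence[DelphiBallot]):
    valid = [b for b in ballots if b.valid]
    rejected = tuple(b.participant_id for b in ballots if not b.valid)
    return valid, rejected


def consensus_estimate(
    ballots: Sequence[DelphiBallot], round_number: int = 1
) -> ConsensusResult:
    """Component-wise median of the valid ballots.

    Ballots with lower > upper (or an unknown density label) are rejected and
    reported in ``rejected``; an even ballot count uses the mean of the
    central pair, the standard median rule.
    """
    if len(ballots) == 0:
        raise EstimationError("no ballots submitted")
    valid, rejected = _split_valid(ballots)
    if not valid:
        raise EstimationError(f"all {len(ballots)} ballots invalid: {rejected}")
    return ConsensusResult(
        point=float(median(b.most_likely for b in valid)),
        lower=float(median(b.lower for b in valid)),
        upper=float(median(b.upper for b in valid)),
        round_number=round_number,
        n_ballots=len(valid),
        rejected=rejected,
    )


def density_label(score: float) -> str:
    """Map a mean density score back to the nearest label.

    Thresholds sit halfway between the codes (1.5 and 2.5); an exact
    boundary rounds up to the denser label.
    """
    if score < 1 or score > 3:
        raise EstimationError(f"density score {score} outside the coded range [1, 3]")
    if score < 1.5:
        return "low"
    if score < 2.5:
        return "medium"
    return "high"


def district_density(ballots: Sequence[DelphiBallot]) -> pd.DataFrame:
    """Per-district mean density score and consensus label.

    Districts named by at least one valid ballot get a mean of the coded
    votes (low=1, medium=2, high=3) and the nearest-label classification;
    ``n_votes`` records how many ballots classified each district, so a
    district every ballot omitted is visibly missing from the frame.
    """
    valid, _ = _split_valid(ballots)
    if not valid:
        raise EstimationError("no valid ballots classify any district")
    votes: dict[str, list[int]] = {}
    for b in valid:
        for district, label in b.district_density.items():
            votes.setdefault(district, []).append(DENSITY_CODES[label])
    if not votes:
        raise EstimationError("no district classifications on any ballot")
    rows = [
        {
            "district": district,
            "mean_score": sum(v) / len(v),
            "label": density_label(sum(v) / len(v)),
            "n_votes": len(v),
        }
        for district, v in sorted(votes.items())
    ]
    return pd.DataFrame(rows)


class DelphiPanel:
    """Multi-round modified-Delphi panel.

    Construct with the round-1 ballots; call :meth:`add_round` with revised
    ballots as further rounds are run, then :meth:`fit`. The consensus of the
    final round is the result; earlier rounds are kept as history only.
    """

    def __init__(self, ballots: Sequence[DelphiBallot], max_rounds: int = 5):
        self.rounds: list[Sequence[DelphiBallot]] = [list(ballots)]
        self.max_rounds = max_rounds

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DelphiPanel":
        from .io import read_ballots

        return cls(read_ballots(path), **kwargs)

    def add_round(self, ballots: Sequence[DelphiBallot]) -> "DelphiPanel":
        if len(self.rounds) >= self.max_rounds:
            raise EstimationError(f"max_rounds={self.max_rounds} already reached")
        self.rounds.append(list(ballots))
        return self

    def fit(self) -> "DelphiResults":
        history = [
            consensus_estimate(ballots, round_number=i + 1)
            for i, ballots in enumerate(self.rounds)
        ]
        final = self.rounds[-1]
        if any(b.district_density for b in final if b.valid):
            densities = district_density(final)
        else:  # a panel may be asked only for the national figures
            densities = pd.DataFrame(columns=["district", "mean_score", "label", "n_votes"])
        return DelphiResults(
            model=self,
            consensus=history[-1],
            history=history,
            densities=densities,
        )


@dataclass
class DelphiResults:
    model: DelphiPanel
    consensus: ConsensusResult
    history: list[ConsensusResult]
    densities: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "consensus": {
                "point": self.consensus.point,
                "lower": self.consensus.lower,
                "upper": self.consensus.upper,
                "round": self.consensus.round_number,
            },
            "rounds": [
                {
                    "round": r.round_number,
                    "point": r.point,
                    "lower": r.lower,
                    "upper": r.upper,
                    "n_ballots": r.n_ballots,
                    "rejected": list(r.rejected),
                }
                for r in self.history
            ],
            "district_density": self.densities.to_dict(orient="records"),
        }

    def summary(self) -> str:
        c = self.consensus
        lines = [
            "Modified-Delphi consensus",
            "=" * 45,
            f"Rounds held: {len(self.history)}   Ballots (final round): {c.n_ballots}",
            f"Consensus estimate: {c.point:.0f}  (plausible {c.lower:.0f}-{c.upper:.0f})",
        ]
        if c.rejected:
            lines.append(f"Rejected ballots: {', '.join(c.rejected)}")
        lines.append("")
        lines.append(f"{'district':<20}{'mean score':>11}{'label':>9}{'votes':>7}")
        for _, r in self.densities.iterrows():
            lines.append(
                f"{r['district']:<20}{r['mean_score']:>11.2f}{r['label']:>9}{r['n_votes']:>7}"
            )
        return "\n".join(lines)
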