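"""Task design parameters for the helping-under-threat paradigm.

The paradigm crosses threat imminence (distal vs. imminent, presented in
blocks) with threat level (safe / 1 shock / 2 shocks) within each functional
run.  On shock trials the participant decides whether to help the
co-participant avoid an upcoming shock; helping carries a fixed probability
that both parties are shocked, while not helping guarantees a shock to the
co-participant only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError

#: Ordered threat levels, from no threat to high threat.
LEVELS = ("safe", "1shock", "2shocks")

#: Imminence conditions.  Distal = decision prompted while the cue is far
#: from the shock moment; imminent = decision prompted just before delivery.
CONDITIONS = ("distal", "imminent")

#: The 13 regions of interest of the ROI-based analysis.
DEFAULT_ROI_LIST = (
    "amygdala_left",
    "amygdala_right",
    "hippocampus_left",
    "hippocampus_right",
    "insula_left",
    "insula_right",
    "midbrain",
    "acc_left",
    "acc_right",
    "vmpfc_left",
    "vmpfc_right",
    "vlpfc_left",
    "vlpfc_right",
)

#: Region whose threat-coding strength drives the helping policy in the
#: synthetic cohort (the headline region of the analysis).
DEFAULT_TARGET_ROI = "amygdala_left"


@dataclass(frozen=True)
class TaskDesign:
    """Counts and contingencies defining one subject's task schedule.

    Defaults reproduce the published design: 8 runs of 18 trials, 9 distal
    and 9 imminent per run presented in two blocks, 6 trials per threat
    level per run (24 per imminence x level cell overall), and a 70 %
    chance that both participants are shocked after a help decision.
    """

    n_runs: int = 8
    trials_per_run: int = 18
    n_distal_per_run: int = 9
    n_imminent_per_run: int = 9
    n_per_level_per_run: int = 6
    levels: tuple[str, ...] = field(default=LEVELS)
    p_both_shocked_on_help: float = 0.70

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise ValidationError("n_runs and trials_per_run must be >= 1")
        if self.n_distal_per_run + self.n_imminent_per_run != self.trials_per_run:
            raise ValidationError(
                f"n_distal_per_run + n_imminent_per_run = "
                f"{self.n_distal_per_run + self.n_imminent_per_run} "
                f"!= trials_per_run = {self.trials_per_run}"
            )
        if self.n_per_level_per_run * len(self.levels) != self.trials_per_run:
            raise ValidationError(
                f"n_per_level_per_run x n_levels = "
                f"{self.n_per_level_per_run * len(self.levels)} "
                f"!= trials_per_run = {self.trials_per_run}"
            )
        if not 0.0 <= self.p_both_shocked_on_help <= 1.0:
            raise ValidationError("p_both_shocked_on_help must lie in [0, 1]")
        for block in (self.n_distal_per_run, self.n_imminent_per_run):
            per_level = block * self.n_per_level_per_run
            if per_level % self.trials_per_run != 0:
                raise ValidationError(
                    "level counts cannot be balanced within each imminence "
                    f"block: block size {block} x {self.n_per_level_per_run} "
                    f"per level is not divisible by {self.trials_per_run}"
                )

    def levels_per_block(self, block_size: int) -> int:
        """Trials per threat level inside one imminence block of a run."""
        return block_size * self.n_per_level_per_run // self.trials_per_run

    @property
    def n_trials(self) -> int:
        """Total trials per subject."""
        return self.n_runs * self.trials_per_run
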