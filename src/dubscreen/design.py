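"""Experiment design: which samples belong to the control and the DUB-silenced arm.

A screen compares biotin-pulldown LFQ intensities between cells treated with a
control siRNA and cells in which one deubiquitinating enzyme (DUB) has been
silenced.  The default layout is three biological replicates per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONTROL = "control"
SILENCED = "silenced"


@dataclass(frozen=True)
class SampleInfo:
    """One MS sample: its LFQ column label, arm, and replicate index (1-based)."""

    label: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in (CONTROL, SILENCED):
            raise ValueError(
                f"condition must be {CONTROL!r} or {SILENCED!r}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample-to-condition mapping for one DUB-silencing experiment.

    Parameters
    ----------
    experiment_id : str
        Unique identifier of the experiment (used by the substrate store).
    dub_name : str
        Gene symbol of the silenced deubiquitinase (e.g. ``"USP9X"``).
    samples : tuple of SampleInfo
        Ordered samples; each ``label`` must match one ``LFQ intensity <label>``
        column of the protein-group table it is applied to.
    """

    experiment_id: str
    dub_name: str
    samples: tuple[SampleInfo, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        for cond in (CONTROL, SILENCED):
            if sum(s.condition == cond for s in self.samples) < 2:
                raise ValueError(f"need at least 2 samples in condition {cond!r}")

    @property
    def sample_labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def labels_for(self, condition: str) -> list[str]:
        return [s.label for s in self.samples if s.condition == condition]

    @property
    def control_labels(self) -> list[str]:
        return self.labels_for(CONTROL)

    @property
    def silenced_labels(self) -> list[str]:
        return self.labels_for(SILENCED)


def default_design(dub_name: str, n_reps: int = 3, experiment_id: str | None = None) -> ExperimentDesign:
    """Triplicate (by default) control vs silenced design with conventional labels.

    Labels are ``ctr_1..ctr_n`` and ``si_1..si_n``, matching the columns the
    synthetic generator writes.
    """
    samples = tuple(
        [SampleInfo(f"ctr_{r}", CONTROL, r) for r in range(1, n_reps + 1)]
        + [SampleInfo(f"si_{r}", SILENCED, r) for r in range(1, n_reps + 1)]
    )
    return ExperimentDesign(
        experiment_id=experiment_id or f"{dub_name}_screen",
        dub_name=dub_name,
        samples=samples,
    )
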