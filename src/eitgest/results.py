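"""Per-run evaluation records."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class EvalResult:
    """One training run: model x split x calibration x seed.

    The headline metric is the best test-set accuracy over training epochs
    (the field's customary — optimistically biased — comparison metric).
    """

    model: str
    split: str
    calibration: str
    seed: int
    test_accuracy: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def best_test_accuracy(self) -> float:
        if not self.test_accuracy:
            raise ValueError("no epochs recorded")
        return max(self.test_accuracy)

    @property
    def best_epoch(self) -> int:
        return int(max(range(len(self.test_accuracy)), key=self.test_accuracy.__getitem__))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["best_test_accuracy"] = self.best_test_accuracy
        d["best_epoch"] = self.best_epoch
        return d
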