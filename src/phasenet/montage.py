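"""Channel montage: ordered labels and hemisphere membership.

Hemisphere assignment follows the 10-20 naming convention: odd-numbered
electrodes sit over the left hemisphere, even-numbered over the right,
and ``z``-suffixed electrodes on the midline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

__all__ = ["Montage", "default_montage", "DEFAULT_LABELS"]

#: 28-channel cap: a 32-electrode 10-20 layout minus reference,
#: mastoids and EOG leads.
DEFAULT_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)


def hemisphere_of_label(label: str) -> str:
    """Classify a 10-20 electrode label as left / right / midline."""
    if label[-1].lower() == "z":
        return "midline"
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot classify electrode label {label!r}")
    return "left" if int(digits) % 2 == 1 else "right"


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with a hemisphere map.

    Parameters
    ----------
    labels
        Ordered, unique channel names; row/column order of every
        association matrix downstream.
    hemisphere_of
        Mapping from label to ``{"left", "right", "midline"}``.  When
        omitted it is derived from the 10-20 naming convention.
    """

    labels: tuple[str, ...]
    hemisphere_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if not self.hemisphere_of:
            object.__setattr__(
                self,
                "hemisphere_of",
                {lab: hemisphere_of_label(lab) for lab in self.labels},
            )
        missing = [lab for lab in self.labels if lab not in self.hemisphere_of]
        if missing:
            raise ValueError(f"labels without hemisphere assignment: {missing}")
        bad = {h for h in self.hemisphere_of.values()} - {"left", "right", "midline"}
        if bad:
            raise ValueError(f"invalid hemisphere values: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def channels_in(self, hemisphere: str) -> list[str]:
        return [lab for lab in self.labels if self.hemisphere_of[lab] == hemisphere]

    def pair_classes(self) -> dict[str, list[tuple[int, int]]]:
        """Index pairs per hemispheric class.

        Returns ``{"left": [...], "right": [...], "inter": [...]}`` with
        (i, j), i < j, in montage order.  Pairs involving midline
        channels belong to no class.
        """
        hemi = [self.hemisphere_of[lab] for lab in self.labels]
        classes: dict[str, list[tuple[int, int]]] = {"left": [], "right": [], "inter": []}
        for i, j in combinations(range(self.n_channels), 2):
            hi, hj = hemi[i], hemi[j]
            if "midline" in (hi, hj):
                continue
            if hi == hj:
                classes[hi].append((i, j))
            else:
                classes["inter"].append((i, j))
        return classes


def default_montage() -> Montage:
    """The default 28-channel montage (12 left, 12 right, 4 midline)."""
    return Montage(labels=DEFAULT_LABELS)
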