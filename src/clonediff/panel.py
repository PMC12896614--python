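"""Clone panels and the four grouping hypotheses.

A clone panel is a set of isogenic cell lines derived from the same parental
line, differing only in which exons of the perturbed gene were disrupted.
Every clone carries one group label under each of four alternative grouping
hypotheses used for contrast testing:

* ``H1`` — binary: ``WT`` vs ``targeted``.
* ``H2`` — by targeted exon(s): ``WT``, ``exon4``, ``exon6``, ``exon4and6``.
* ``H3`` — protein-informed: ``WT``, ``exon4-low``, ``exon4-high``,
  ``exon6``, ``double`` (exon-4 clones split by detectable protein level).
* ``H4`` — number of targeted exons: ``0``, ``1``, ``2`` (a proxy for the
  number of intact DNA-binding zinc fingers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

HYPOTHESES = ("H1", "H2", "H3", "H4")


class InvalidConfigError(ValueError):
    """Raised when a panel or pipeline configuration is not usable."""


@dataclass(frozen=True)
class ClonePanel:
    """Clone identifiers with group labels under each grouping hypothesis.

    Parameters
    ----------
    labels
        DataFrame indexed by clone id with exactly the columns
        ``H1, H2, H3, H4`` holding string group labels.
    """

    labels: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [h for h in HYPOTHESES if h not in self.labels.columns]
        if missing:
            raise InvalidConfigError(f"panel missing hypothesis columns: {missing}")
        if self.labels.index.duplicated().any():
            raise InvalidConfigError("duplicate clone identifiers in panel")
        if len(self.labels) < 2:
            raise InvalidConfigError("a panel needs at least 2 clones")

    @property
    def clones(self) -> list[str]:
        return list(self.labels.index)

    def __len__(self) -> int:
        return len(self.labels)

    def groups(self, hypothesis: str) -> pd.Series:
        """Group label per clone under one hypothesis."""
        if hypothesis not in HYPOTHESES:
            raise KeyError(f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES}")
        return self.labels[hypothesis]

    def group_sizes(self, hypothesis: str) -> pd.Series:
        return self.groups(hypothesis).value_counts()

    def to_tsv(self, path) -> None:
        self.labels.to_csv(path, sep="\t", index_label="clone")

    @classmethod
    def from_tsv(cls, path) -> "ClonePanel":
        return cls(pd.read_csv(path, sep="\t", index_col="clone", dtype=str))
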