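"""Individual-level cohort container.

A :class:`Cohort` holds one record per person: age at entry into the risk
set (delayed entry / left truncation), age at exit (death or censoring),
and a terminal status that is either the censoring label or one of the
death-cause labels.  Ages are continuous (fractional years allowed).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Cohort"]


class Cohort:
    """Right-censored, left-truncated survival data with competing causes.

    Parameters
    ----------
    entry : array-like of float
        Age at start of follow-up for each person (years, >= 0).  Persons
        followed from birth have entry 0.
    exit : array-like of float
        Age at death or censoring (years).  Must exceed ``entry``
        element-wise; zero-length intervals are rejected.
    status : array-like of str
        Terminal status: the censoring label (``censor_label``) or one of
        the death-cause labels.
    cause_labels : sequence of str, optional
        Ordered death-cause categories.  Inferred from ``status`` (order
        of first appearance) when omitted.
    censor_label : str
        Reserved status value marking censored observations.
    onset : array-like of float, optional
        Age at disease onset per person; ``nan`` for persons who never
        develop the disease.
    """

    def __init__(
        self,
        entry,
        exit,
        status,
        cause_labels: Sequence[str] | None = None,
        censor_label: str = "alive",
        onset=None,
    ) -> None:
        self.entry = np.asarray(entry, dtype=float)
        self.exit = np.asarray(exit, dtype=float)
        self.status = np.asarray(status, dtype=object)
        self.censor_label = str(censor_label)
        if self.entry.ndim != 1 or self.entry.shape != self.exit.shape or self.entry.shape != self.status.shape:
            raise ValueError("entry, exit and status must be 1-d arrays of equal length")
        if self.entry.size == 0:
            raise ValueError("cohort is empty")
        if np.any(~np.isfinite(self.entry)) or np.any(~np.isfinite(self.exit)):
            raise ValueError("entry and exit ages must be finite")
        if np.any(self.entry < 0):
            raise ValueError("entry ages must be non-negative")
        bad = np.flatnonzero(self.exit <= self.entry)
        if bad.size:
            raise ValueError(
                f"exit age must exceed entry age; violated at record(s) {bad[:10].tolist()}"
            )

        observed = [s for s in dict.fromkeys(self.status.tolist()) if s != self.censor_label]
        if cause_labels is None:
            cause_labels = observed
        cause_labels = [str(c) for c in cause_labels]
        if len(set(cause_labels)) != len(cause_labels):
            raise ValueError("cause labels must be unique")
        if any(not c for c in cause_labels):
            raise ValueError("cause labels must be non-empty strings")
        if self.censor_label in cause_labels:
            raise ValueError("censoring label cannot also be a cause label")
        unknown = set(observed) - set(cause_labels)
        if unknown:
            raise ValueError(f"unknown status values: {sorted(unknown)}")
        self.cause_labels: tuple[str, ...] = tuple(cause_labels)

        # -1 = censored, otherwise index into cause_labels
        lut = {c: i for i, c in enumerate(self.cause_labels)}
        lut[self.censor_label] = -1
        self.cause_index = np.fromiter(
            (lut[s] for s in self.status), dtype=np.int64, count=self.status.size
        )

        if onset is not None:
            onset = np.asarray(onset, dtype=float)
            if onset.shape != self.entry.shape:
                raise ValueError("onset must have one value (possibly nan) per record")
            with np.errstate(invalid="ignore"):
                if np.any(onset[np.isfinite(onset)] < 0):
                    raise ValueError("onset ages must be non-negative")
        self.onset = onset

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.entry.size

    def __len__(self) -> int:
        return self.n

    def subset(self, mask) -> "Cohort":
        mask = np.asarray(mask)
        return Cohort(
            self.entry[mask],
            self.exit[mask],
            self.status[mask],
            cause_labels=self.cause_labels,
            censor_label=self.censor_label,
            onset=None if self.onset is None else self.onset[mask],
        )

    def diseased(self) -> "Cohort":
        """Sub-cohort of persons with a recorded disease onset.

        Follow-up for the returned cohort starts at the onset age (the
        landmark that avoids immortal time bias: a person must survive to
        onset to be observed with the disease).
        """
        if self.onset is None:
            raise ValueError("cohort carries no onset ages")
        mask = np.isfinite(self.onset)
        if not mask.any():
            raise ValueError("no diseased persons in cohort")
        return Cohort(
            self.onset[mask],
            self.exit[mask],
            self.status[mask],
            cause_labels=self.cause_labels,
            censor_label=self.censor_label,
            onset=self.onset[mask],
        )

    def summary(self) -> dict:
        """Ingestion-style counts: totals, deaths by cause, censored, diseased."""
        out = {
            "n": int(self.n),
            "censored": int(np.sum(self.cause_index < 0)),
        }
        for i, c in enumerate(self.cause_labels):
            out[f"deaths_{c}"] = int(np.sum(self.cause_index == i))
        if self.onset is not None:
            out["diseased"] = int(np.sum(np.isfinite(self.onset)))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Cohort(n={self.n}, causes={list(self.cause_labels)}, "
            f"censor_label={self.censor_label!r})"
        )
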