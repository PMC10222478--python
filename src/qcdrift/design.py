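"""Acquisition-sequence design checks and boundary-QC handling.

A well-designed run starts with conditioning QC injections (column
equilibration only), places a pooled QC between every few biological
samples, and doubles the QCs at the sequence boundaries so that a failed
boundary injection does not force the drift model to extrapolate.  The
validator encodes the common recommendations as soft findings -- it
never rejects a design, it only warns.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import (
    ROLE_BIOLOGICAL,
    ROLE_CONDITIONING,
    ROLE_QC,
    FeatureTable,
)


@dataclass(frozen=True)
class ValidationPolicy:
    """Thresholds for :func:`validate_design`.

    max_spacing
        Warn when more than this many biological samples sit between
        consecutive QCs (rule of thumb: a QC every 3rd to 10th sample).
    advise_spacing
        Informational note when spacing exceeds this but stays legal.
    min_qcs
        Minimum number of non-conditioning QCs in the sequence.
    min_conditioning
        Minimum number of leading conditioning injections.
    boundary_qcs
        Expected number of adjacent QCs at each sequence boundary.
    """

    max_spacing: int = 10
    advise_spacing: int = 7
    min_qcs: int = 8
    min_conditioning: int = 5
    boundary_qcs: int = 2


@dataclass(frozen=True)
class Finding:
    level: str  # "warn" | "info"
    rule: str
    message: str


@dataclass
class SequenceDesign:
    """Ordered (injection_order, role) list with derived design facts."""

    entries: list  # [(injection_order, role), ...] sorted by order

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e[0])

    @classmethod
    def from_table(cls, table: FeatureTable, batch=None) -> "SequenceDesign":
        meta = table.samples
        if batch is not None:
            meta = meta[meta["batch"] == batch]
        return cls(list(zip(meta["injection_order"], meta["role"])))

    @property
    def roles(self) -> list:
        return [r for _, r in self.entries]

    @property
    def n_qc(self) -> int:
        return sum(r == ROLE_QC for r in self.roles)

    @property
    def n_conditioning(self) -> int:
        """Count of the *leading* conditioning injections."""
        n = 0
        for r in self.roles:
            if r == ROLE_CONDITIONING:
                n += 1
            else:
                break
        return n

    @property
    def qc_spacing(self) -> int:
        """Max biological samples between consecutive QCs (including the
        stretches before the first and after the last QC)."""
        longest = run = 0
        for r in self.roles:
            if r == ROLE_BIOLOGICAL:
                run += 1
                longest = max(longest, run)
            elif r == ROLE_QC:
                run = 0
        return longest

    @property
    def boundary_qc_counts(self) -> tuple:
        """(leading, trailing) adjacent QC counts, conditioning skipped."""
        core = [r for r in self.roles if r != ROLE_CONDITIONING]
        lead = trail = 0
        for r in core:
            if r == ROLE_QC:
                lead += 1
            else:
                break
        for r in reversed(core):
            if r == ROLE_QC:
                trail += 1
            else:
                break
        if lead == len(core):  # all-QC design: one boundary
            trail = lead
        return lead, trail


def validate_design(design: SequenceDesign, policy: ValidationPolicy | None = None) -> list:
    """Check a sequence design against QC-placement recommendations.

    Returns a list of :class:`Finding`; empty when fully compliant.
    Never raises on content.
    """
    policy = policy or ValidationPolicy()
    if not design.entries:
        return [Finding("info", "empty_design", "design contains no samples")]
    findings = []
    spacing = design.qc_spacing
    if spacing > policy.max_spacing:
        findings.append(Finding(
            "warn", "qc_spacing",
            f"up to {spacing} biological samples between QCs "
            f"(recommended at most {policy.max_spacing})",
        ))
    elif spacing > policy.advise_spacing:
        findings.append(Finding(
            "info", "qc_spacing",
            f"{spacing} biological samples between QCs; "
            f"{policy.advise_spacing} or fewer is preferable",
        ))
    if design.n_qc < policy.min_qcs:
        findings.append(Finding(
            "warn", "min_qcs",
            f"only {design.n_qc} QCs in sequence (recommended at least "
            f"{policy.min_qcs}, conditioning excluded)",
        ))
    if design.n_conditioning < policy.min_conditioning:
        findings.append(Finding(
            "warn", "conditioning",
            f"only {design.n_conditioning} leading conditioning QCs "
            f"(recommended at least {policy.min_conditioning})",
        ))
    lead, trail = design.boundary_qc_counts
    if lead < policy.boundary_qcs:
        findings.append(Finding(
            "warn", "boundary_qcs",
            f"{lead} QCs at sequence start (recommended {policy.boundary_qcs})",
        ))
    if trail < policy.boundary_qcs:
        findings.append(Finding(
            "warn", "boundary_qcs",
            f"{trail} QCs at sequence end (recommended {policy.boundary_qcs})",
        ))
    return findings


def dedup_boundary_qcs(table: FeatureTable) -> FeatureTable:
    """Keep one QC of each duplicated boundary pair per batch.

    Doubled boundary QCs are an insurance against injection failure;
    when both ran, only one should enter correction and metrics.  For a
    run of adjacent QCs opening a batch the *first* keeps role ``qc``;
    for a run closing a batch the *last* does.  The others are relabeled
    ``conditioning_qc``, which downstream code ignores.  Idempotent.
    """
    out = table.copy()
    roles = out.samples["role"]
    for b in out.batches():
        in_batch = out.samples["batch"] == b
        # adjacency judged on the batch's non-conditioning rows, in order
        core_idx = out.samples.index[in_batch & (roles != ROLE_CONDITIONING)]
        core_roles = roles.loc[core_idx].tolist()
        lead = 0
        while lead < len(core_roles) and core_roles[lead] == ROLE_QC:
            lead += 1
        if lead == len(core_roles):
            continue  # batch of only QCs: leave alone
        trail = 0
        while trail < len(core_roles) and core_roles[-1 - trail] == ROLE_QC:
            trail += 1
        demote = []
        if lead >= 2:
            demote.extend(core_idx[1:lead])       # keep the first
        if trail >= 2:
            demote.extend(core_idx[len(core_idx) - trail:len(core_idx) - 1])
        out.samples.loc[demote, "role"] = ROLE_CONDITIONING
    return out
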