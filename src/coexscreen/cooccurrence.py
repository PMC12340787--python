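"""Monte Carlo permutation test for candidate/substrate module co-occurrence.

Given per-cell-type module assignments, a network is *eligible* when the two
substrate genes (the collagen IV subunit pair) carry the same module label,
excluding "unassigned".  The empirical statistic is the number of eligible
networks in which a candidate gene shares that module.  Significance is
assessed by randomisation: module assignments are shuffled within each
network (preserving module sizes), a candidate is drawn at random from the
candidate list in each replicate, and the p-value is the proportion of
replicates whose match count is at least the empirical value.  With zero
exceedances the p-value is reported as "< 1/N".

Two null modes cover the two natural readings of "randomise the
assignments":

* ``shuffle_all`` (default) — every network's full gene -> module vector is
  permuted each replicate, so both the substrate pair's eligibility and the
  candidate's placement are randomised.
* ``random_candidate_slot`` — eligibility is held at its observed value and
  only the candidate is dropped into a uniformly random gene slot of each
  eligible network.

An exact oracle (:func:`exact_cooccurrence_pvalue`) computes the same tail
probability analytically from the module-size profiles: per network the
match event is Bernoulli, and the tail of the sum of independent Bernoullis
is obtained by brute-force convolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpecificationError

__all__ = [
    "UNASSIGNED",
    "NetworkProfile",
    "eligible_networks",
    "count_coassignment",
    "ModuleCooccurrenceTest",
    "CooccurrenceResult",
    "permutation_test",
    "exact_cooccurrence_pvalue",
    "profiles_from_assignments",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
NULL_MODES = ("shuffle_all", "random_candidate_slot")


def eligible_networks(
    assignments: Mapping[str, pd.Series], substrate_pair: tuple[str, str]
) -> list[str]:
    """Groups whose substrate pair shares one non-"unassigned" module."""
    a, b = substrate_pair
    eligible = []
    for group, assignment in assignments.items():
        if a not in assignment.index or b not in assignment.index:
            logger.info(
                "group %r skipped: substrate pair absent from its gene universe",
                group,
            )
            continue
        if assignment[a] == assignment[b] != UNASSIGNED:
            eligible.append(group)
    return eligible


def count_coassignment(
    assignments: Mapping[str, pd.Series],
    substrate_pair: tuple[str, str],
    candidate: str,
) -> int:
    """Eligible networks in which the candidate shares the pair's module."""
    if candidate in substrate_pair:
        raise SpecificationError(
            f"candidate {candidate!r} is one of the substrate genes"
        )
    matches = 0
    for group in eligible_networks(assignments, substrate_pair):
        assignment = assignments[group]
        if candidate not in assignment.index:
            logger.info("group %r: candidate %r absent, contributes 0", group, candidate)
            continue
        if assignment[candidate] == assignment[substrate_pair[0]]:
            matches += 1
    return matches


@dataclass
class CooccurrenceResult:
    """Outcome of the co-occurrence permutation test for one candidate."""

    candidate: str
    empirical_matches: int
    n_eligible_networks: int
    n_permutations: int
    p_value: float
    p_report: str
    seed: int
    null_mode: str

    def summary(self) -> str:
        return "\n".join(
            [
                "Module co-occurrence permutation test",
                f"  candidate: {self.candidate}",
                f"  networks (cell types) with candidate/substrate co-expression: "
                f"{self.empirical_matches}",
                f"  networks (cell types) with substrate-pair co-expression: "
                f"{self.n_eligible_networks}",
                f"  p {self.p_report}  ({self.n_permutations} replicates, "
                f"null mode {self.null_mode}, seed {self.seed})",
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "candidate": self.candidate,
                    "matches": self.empirical_matches,
                    "eligible_networks": self.n_eligible_networks,
                    "n_permutations": self.n_permutations,
                    "p_value": self.p_value,
                    "p_report": self.p_report,
                    "null_mode": self.null_mode,
                    "seed": self.seed,
                }
            ]
        )


class ModuleCooccurrenceTest:
    """Model object for the co-occurrence test of one focal candidate.

    Parameters
    ----------
    assignments:
        Mapping group label -> gene -> module assignment (one per network).
    substrate_pair:
        The two substrate gene symbols (e.g. the collagen IV subunits).
    candidates:
        Candidate pool from which one gene is redrawn per replicate.
    candidate:
        The focal candidate whose empirical match count is tested.
    null_mode:
        ``shuffle_all`` or ``random_candidate_slot`` (see module docstring).
    """

    def __init__(
        self,
        assignments: Mapping[str, pd.Series],
        substrate_pair: tuple[str, str],
        candidates: Sequence[str],
        candidate: str,
        null_mode: str = "shuffle_all",
    ) -> None:
        if not candidates:
            raise SpecificationError("candidate list must be nonempty")
        if null_mode not in NULL_MODES:
            raise SpecificationError(f"null_mode must be one of {NULL_MODES}")
        for gene in (candidate, *candidates):
            if gene in substrate_pair:
                raise SpecificationError(
                    f"candidate {gene!r} is one of the substrate genes"
                )
        self.assignments = dict(assignments)
        self.substrate_pair = tuple(substrate_pair)
        self.candidates = list(candidates)
        self.candidate = candidate
        self.null_mode = null_mode

    def fit(self, n_permutations: int = 10_000, seed: int = 0) -> CooccurrenceResult:
        if n_permutations < 1:
            raise SpecificationError("n_permutations must be >= 1")
        empirical = count_coassignment(
            self.assignments, self.substrate_pair, self.candidate
        )
        eligible = eligible_networks(self.assignments, self.substrate_pair)
        rng = np.random.default_rng(seed)

        # integer-coded assignments per group; "unassigned" -> -1
        groups = []
        for group, assignment in self.assignments.items():
            genes = list(assignment.index)
            labels = assignment.to_numpy()
            uniq = [u for u in pd.unique(labels) if u != UNASSIGNED]
            code = {u: i for i, u in enumerate(uniq)}
            code[UNASSIGNED] = -1
            codes = np.array([code[l] for l in labels], dtype=np.int64)
            pos = {g: i for i, g in enumerate(genes)}
            ia = pos.get(self.substrate_pair[0], -1)
            ib = pos.get(self.substrate_pair[1], -1)
            cand_pos = np.array(
                [pos.get(c, -1) for c in self.candidates], dtype=np.int64
            )
            groups.append((group, codes, ia, ib, cand_pos))

        exceed = 0
        if self.null_mode == "shuffle_all":
            cand_draw = rng.integers(0, len(self.candidates), size=n_permutations)
            for rep in range(n_permutations):
                ci = cand_draw[rep]
                total = 0
                for _, codes, ia, ib, cand_pos in groups:
                    if ia < 0 or ib < 0:
                        continue
                    permuted = codes[rng.permutation(codes.size)]
                    a = permuted[ia]
                    if a >= 0 and permuted[ib] == a:
                        ic = cand_pos[ci]
                        if ic >= 0 and permuted[ic] == a:
                            total += 1
                if total >= empirical:
                    exceed += 1
        else:  # random_candidate_slot: eligibility fixed at observed
            slot_groups = []
            for group, codes, ia, ib, _ in groups:
                if group in eligible:
                    slot_groups.append((codes, codes[ia]))
            for _ in range(n_permutations):
                total = 0
                for codes, module_code in slot_groups:
                    slot = rng.integers(0, codes.size)
                    if codes[slot] == module_code:
                        total += 1
                if total >= empirical:
                    exceed += 1

        p_value = exceed / n_permutations
        if exceed == 0:
            p_report = f"<{1.0 / n_permutations:g}"
        else:
            p_report = f"={p_value:.4g}"
        return CooccurrenceResult(
            candidate=self.candidate,
            empirical_matches=empirical,
            n_eligible_networks=len(eligible),
            n_permutations=n_permutations,
            p_value=p_value,
            p_report=p_report,
            seed=seed,
            null_mode=self.null_mode,
        )


def permutation_test(
    assignments: Mapping[str, pd.Series],
    substrate_pair: tuple[str, str],
    candidates: Sequence[str],
    candidate: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    null_mode: str = "shuffle_all",
) -> CooccurrenceResult:
    """Functional wrapper around :class:`ModuleCooccurrenceTest`."""
    return ModuleCooccurrenceTest(
        assignments, substrate_pair, candidates, candidate, null_mode
    ).fit(n_permutations=n_permutations, seed=seed)


@dataclass
class NetworkProfile:
    """Module-size profile of one network for the exact oracle.

    ``module_sizes`` maps module label -> member count (the "unassigned"
    pool, if present, uses the literal label); ``substrate_module`` is the
    label shared by the substrate pair in the observed assignment, or None
    when the pair is split.
    """

    module_sizes: dict[str, int]
    substrate_module: str | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.module_sizes.values()):
            raise SpecificationError("every module needs >= 1 member")
        if (
            self.substrate_module is not None
            and self.substrate_module not in self.module_sizes
        ):
            raise SpecificationError(
                f"substrate module {self.substrate_module!r} not in size profile"
            )

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes.values())

    def match_probability(self, null_mode: str) -> float:
        """Probability that one network contributes a match per replicate."""
        n = self.n_genes
        if null_mode == "shuffle_all":
            # P(pair together in a real module AND candidate with them)
            # under a uniform assignment permutation: an ordered triple of
            # distinct slots all inside the same module.
            if n < 3:
                return 0.0
            total = 0.0
            for label, s in self.module_sizes.items():
                if label == UNASSIGNED:
                    continue
                total += s * (s - 1) * (s - 2)
            return total / (n * (n - 1) * (n - 2))
        if null_mode == "random_candidate_slot":
            if self.substrate_module is None or self.substrate_module == UNASSIGNED:
                return 0.0
            return self.module_sizes[self.substrate_module] / n
        raise SpecificationError(f"null_mode must be one of {NULL_MODES}")


def profiles_from_assignments(
    assignments: Mapping[str, pd.Series], substrate_pair: tuple[str, str]
) -> list[NetworkProfile]:
    """Build exact-oracle profiles from observed assignments."""
    profiles = []
    a, b = substrate_pair
    for assignment in assignments.values():
        sizes = assignment.value_counts().to_dict()
        substrate_module = None
        if a in assignment.index and b in assignment.index:
            if assignment[a] == assignment[b] != UNASSIGNED:
                substrate_module = str(assignment[a])
        profiles.append(
            NetworkProfile(
                module_sizes={str(k): int(v) for k, v in sizes.items()},
                substrate_module=substrate_module,
            )
        )
    return profiles


def exact_cooccurrence_pvalue(
    profiles: Sequence[NetworkProfile],
    empirical_matches: int,
    null_mode: str = "shuffle_all",
) -> float:
    """Exact tail probability P(matches >= empirical) across networks.

    Each network contributes an independent Bernoulli match with probability
    from its size profile; the distribution of the sum is built by
    convolution and the upper tail returned.  ``empirical_matches = 0``
    gives 1 by construction.
    """
    if empirical_matches < 0:
        raise SpecificationError("empirical_matches must be >= 0")
    pmf = np.array([1.0])
    for profile in profiles:
        p = profile.match_probability(null_mode)
        new = np.zeros(pmf.size + 1)
        new[: pmf.size] += pmf * (1.0 - p)
        new[1:] += pmf * p
        pmf = new
    if empirical_matches >= pmf.size:
        return 0.0
    return float(pmf[empirical_matches:].sum())
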