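"""SBS-96 mutation spectra, signature exposure refitting, artifact flagging.

Exposures are obtained by refitting observed spectra against a fixed
signature catalog (constrained least squares on the probability simplex)
rather than de novo extraction: refitting is deterministic and behaves
sensibly at per-sample mutation counts, where de novo NMF is unstable.
The bundled catalog carries clock-like (SBS1/SBS5-like), POLE-driven
(SBS10b-like), flat, and sequencing-artifact-like components; samples in
which artifact signatures explain more than half of the spectrum are
excluded from downstream mutation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical COSMIC ordering of the 96 single-base-substitution classes
CONTEXTS_96: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def fold_to_pyrimidine(ref: str, alt: str, trinuc: str) -> str | None:
    """SBS-96 class of a substitution, folding purine refs to the
    pyrimidine strand.  Returns None for non-SNVs or contexts with N."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if "N" in trinuc or len(trinuc) != 3:
        return None
    if ref in PYRIMIDINES:
        five, three = trinuc[0], trinuc[2]
    else:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[trinuc[2]], _COMPLEMENT[trinuc[0]]
    key = f"{five}[{ref}>{alt}]{three}"
    return key if key in _CONTEXT_INDEX else None


@dataclass
class SignatureCatalog:
    """96 x K column-stochastic signature matrix with artifact labels."""

    names: list[str]
    matrix: np.ndarray  # shape (96, K), columns sum to 1
    artifact_ids: set[str] = field(default_factory=set)
    contexts: list[str] = field(default_factory=lambda: list(CONTEXTS_96))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("catalog matrix must be 96 x K")
        if (self.matrix < 0).any():
            raise ValueError("signature weights must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("each signature column must sum to 1")
        unknown = self.artifact_ids - set(self.names)
        if unknown:
            raise ValueError(f"artifact ids not in catalog: {sorted(unknown)}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.contexts, columns=self.names)


@dataclass
class ExposureVector:
    """Per-signature exposure fractions for one sample."""

    sample_id: str
    exposures: dict[str, float]
    n_mutations: int
    residual: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_mutations > 0:
            total = sum(self.exposures.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"exposures sum to {total}, not 1")
            if any(v < -1e-12 for v in self.exposures.values()):
                raise ValueError("exposures must be nonnegative")

    def dominant_signature(self, tie_gap: float = 0.05) -> tuple[str, bool]:
        """Max-exposure signature and whether it is a near-tie (gap below
        ``tie_gap`` to the runner-up)."""
        ordered = sorted(self.exposures.items(), key=lambda kv: (-kv[1], kv[0]))
        near_tie = len(ordered) > 1 and ordered[0][1] - ordered[1][1] < tie_gap
        return ordered[0][0], near_tie


def _peaked(classes: dict[str, float], background: float = 0.0) -> np.ndarray:
    w = np.full(96, background, dtype=float)
    for ctx, weight in classes.items():
        w[_CONTEXT_INDEX[ctx]] += weight
    return w / w.sum()


def default_catalog() -> SignatureCatalog:
    """Bundled five-signature fixture catalog.

    SBS1-like (deamination C>T at NpCpG), SBS5-like (broad, T>C-leaning),
    SBS10b-like (POLE, C>T at TpCpT), a flat background, and an
    artifact-like component (T>G-heavy, mimicking sequencing artifacts
    such as SBS49-class signatures).
    """
    sbs1 = _peaked(
        {f"{b}[C>T]G": 1.0 for b in BASES},
        background=0.05 / 92,
    )
    # broad clock-like signature: all classes populated, T>C enriched
    sbs5 = np.ones(96)
    for five in BASES:
        for three in BASES:
            sbs5[_CONTEXT_INDEX[f"{five}[T>C]{three}"]] = 4.0
    sbs5 = sbs5 / sbs5.sum()
    sbs10b = _peaked({"T[C>T]T": 6.0, "T[C>T]G": 1.0, "C[C>T]T": 1.0},
                     background=0.02 / 93)
    flat = np.full(96, 1.0 / 96)
    artifact = _peaked(
        {f"{b}[T>G]T": 1.0 for b in BASES},
        background=0.10 / 92,
    )
    matrix = np.column_stack([sbs1, sbs5, sbs10b, flat, artifact])
    return SignatureCatalog(
        names=["SBS1_like", "SBS5_like", "SBS10b_like", "FLAT", "ARTIFACT"],
        matrix=matrix,
        artifact_ids={"ARTIFACT"},
    )


def context_count_vector(variants: pd.DataFrame, sample_id: str) -> np.ndarray:
    """SBS-96 count vector for one sample.

    Only single-nucleotide substitutions contribute; indels and variants
    whose trinucleotide context contains N are skipped (with a warning
    for the latter).
    """
    counts = np.zeros(96, dtype=int)
    sub = variants[(variants["sample_id"] == sample_id)
                   & (variants["alt_count"] > 0)]
    for ref, alt, ctx, effect in zip(sub["ref"], sub["alt"],
                                     sub["trinuc_context"], sub["effect"]):
        if effect == "indel" or len(ref) != 1 or len(alt) != 1:
            continue
        if "N" in str(ctx):
            warnings.warn(f"skipping variant with ambiguous context {ctx!r}")
            continue
        key = fold_to_pyrimidine(ref, alt, str(ctx))
        if key is not None:
            counts[_CONTEXT_INDEX[key]] += 1
    return counts


def refit_signature_exposures(counts: np.ndarray, catalog: SignatureCatalog,
                              sample_id: str = "sample") -> ExposureVector:
    """Refit exposures by least squares on the probability simplex.

    Minimizes ``|| counts/sum(counts) - M e ||_2`` subject to ``e >= 0``
    and ``sum(e) = 1``.  Deterministic.  If two catalog columns in the
    solution's support are (near-)identical the split between them is not
    identifiable; the result is flagged degenerate rather than silently
    resolved.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError("counts must be a 96-vector")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot refit exposures for an all-zero spectrum")
    p = counts / total
    M = catalog.matrix
    K = M.shape[1]

    def objective(e: np.ndarray) -> float:
        r = p - M @ e
        return float(r @ r)

    def grad(e: np.ndarray) -> np.ndarray:
        return -2.0 * M.T @ (p - M @ e)

    x0 = np.full(K, 1.0 / K)
    res = optimize.minimize(
        objective, x0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0,
                      "jac": lambda e: np.ones(K)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    e = np.clip(res.x, 0.0, None)
    e = e / e.sum()
    residual = float(np.linalg.norm(p - M @ e))

    degenerate = False
    support = [k for k in range(K) if e[k] > 1e-6]
    for i_pos, i in enumerate(support):
        for j in support[i_pos + 1:]:
            ci, cj = M[:, i], M[:, j]
            cos = ci @ cj / (np.linalg.norm(ci) * np.linalg.norm(cj))
            if cos > 1.0 - 1e-9:
                degenerate = True
    return ExposureVector(
        sample_id=sample_id,
        exposures={name: float(e[k]) for k, name in enumerate(catalog.names)},
        n_mutations=int(total),
        residual=residual,
        degenerate=degenerate,
    )


def flag_artifact_samples(exposures: list[ExposureVector],
                          catalog: SignatureCatalog,
                          threshold: float = 0.5) -> set[str]:
    """Samples whose summed artifact-signature exposure strictly exceeds
    ``threshold`` (default 0.5); these are excluded from mutation-based
    analyses including phylogeny."""
    excluded = set()
    for ev in exposures:
        artifact_total = sum(ev.exposures.get(a, 0.0) for a in catalog.artifact_ids)
        if artifact_total > threshold:
            excluded.add(ev.sample_id)
    return excluded
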