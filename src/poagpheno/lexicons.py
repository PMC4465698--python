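"""Configurable code sets and term lists that parameterize the algorithm.

The default lexicon reconstructs the published rule set: the POAG ICD-9 code
365.11, the ICD-9 365.x glaucoma family as "any glaucoma code", the
ophthalmology / general-clinic CPT codes, the seven glaucoma spelling
variants searched in free text, the control-review terms, the POAG surgery
phrases, and the age / blood-pressure / window thresholds.  Drug lists ship
as documented reconstructions of the standard classes.  Every field can be
overridden from a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["AlgorithmLexicon", "load_lexicon", "is_glaucoma_icd9", "default_lexicon"]


@dataclass(frozen=True)
class AlgorithmLexicon:
    poag_icd9: str = "365.11"
    glaucoma_icd9_prefix: str = "365."
    ophtho_cpt: frozenset[str] = frozenset()
    general_clinic_cpt: frozenset[str] = frozenset()
    fundus_cpt: frozenset[str] = frozenset()
    glaucoma_spelling_variants: tuple[str, ...] = ()
    control_review_terms: tuple[str, ...] = ()
    glaucoma_medications: tuple[str, ...] = ()
    poag_surgery_phrases: tuple[str, ...] = ()
    other_subtype_labels: tuple[tuple[str, tuple[str, ...]], ...] = ()
    ambiguity_phrases: tuple[str, ...] = ()
    hypertension_medications: tuple[str, ...] = ()
    case_min_age: int = 20
    control_min_age: int = 40
    sbp_threshold: float = 140.0
    dbp_threshold: float = 90.0
    covariate_window_days: int = 730

    def __post_init__(self) -> None:
        if not self.poag_icd9.startswith(self.glaucoma_icd9_prefix):
            raise ValueError(
                f"poag_icd9 {self.poag_icd9!r} must start with glaucoma_icd9_prefix "
                f"{self.glaucoma_icd9_prefix!r}"
            )
        for name in ("case_min_age", "control_min_age", "sbp_threshold",
                     "dbp_threshold", "covariate_window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.glaucoma_spelling_variants:
            raise ValueError("glaucoma_spelling_variants must be non-empty")
        for listname in ("glaucoma_spelling_variants", "control_review_terms",
                         "glaucoma_medications", "poag_surgery_phrases",
                         "ambiguity_phrases", "hypertension_medications"):
            for phrase in getattr(self, listname):
                if phrase != phrase.lower():
                    raise ValueError(f"{listname} entry {phrase!r} must be lowercase")
        for _, phrases in self.other_subtype_labels:
            for phrase in phrases:
                if phrase != phrase.lower():
                    raise ValueError(f"other_subtype_labels entry {phrase!r} must be lowercase")

    @property
    def subtype_labels(self) -> dict[str, tuple[str, ...]]:
        return dict(self.other_subtype_labels)

    @property
    def eligibility_cpt(self) -> frozenset[str]:
        """CPT codes that satisfy the screening requirement (ophtho or general clinic)."""
        return self.ophtho_cpt | self.general_clinic_cpt


def _freeze(raw: dict) -> dict:
    out = dict(raw)
    for key in ("ophtho_cpt", "general_clinic_cpt", "fundus_cpt"):
        if key in out:
            out[key] = frozenset(str(c) for c in out[key])
    for key in ("glaucoma_spelling_variants", "control_review_terms",
                "glaucoma_medications", "poag_surgery_phrases",
                "ambiguity_phrases", "hypertension_medications"):
        if key in out:
            out[key] = tuple(str(t) for t in out[key])
    if "other_subtype_labels" in out:
        out["other_subtype_labels"] = tuple(
            (str(label), tuple(str(p) for p in phrases))
            for label, phrases in out["other_subtype_labels"].items()
        )
    return out


def _default_raw() -> dict:
    text = resources.files("poagpheno.data").joinpath("default_lexicon.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def default_lexicon() -> AlgorithmLexicon:
    """The shipped defaults, with no overrides."""
    return AlgorithmLexicon(**_freeze(_default_raw()))


def load_lexicon(path: str | Path | None = None) -> AlgorithmLexicon:
    """Load the lexicon, merging an optional YAML override file over the defaults.

    Raises ``ValueError`` naming the violated rule if an override breaks a
    lexicon invariant, and on unknown keys.
    """
    raw = _default_raw()
    if path is not None:
        override = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        known = {f.name for f in fields(AlgorithmLexicon)}
        unknown = set(override) - known
        if unknown:
            raise ValueError(f"unknown lexicon keys in {path}: {sorted(unknown)}")
        raw.update(override)
    return AlgorithmLexicon(**_freeze(raw))


def is_glaucoma_icd9(code: str, lexicon: AlgorithmLexicon) -> bool:
    """True iff *code* falls in the configured glaucoma ICD-9 family (365.x)."""
    if not code:
        raise ValueError("code must be non-empty")
    return code.startswith(lexicon.glaucoma_icd9_prefix)


def with_overrides(lexicon: AlgorithmLexicon, **kwargs) -> AlgorithmLexicon:
    """Functional update helper; re-runs invariant checks."""
    return replace(lexicon, **kwargs)
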