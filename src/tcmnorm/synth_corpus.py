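"""Synthetic prescription corpora with the structure of TCM clinical data.

Real standard/clinical symptom vocabularies and prescription records are
not redistributable, so this module generates corpora that reproduce their
load-bearing statistical features:

* symptom names are short concatenations of 1-2-character tokens for the
  affected body part, the disease property and the disease degree; about
  two thirds of names contain a body part and, when present, it is almost
  always the prefix on the standard side but less reliably so on the
  clinical side;
* most standard names have more than one clinical variant (synonym
  substitution, body-part relocation, degree omission, character noise);
* each standard name owns a remedy signature; prescriptions sample from
  the owner's signature with dropout and spurious additions, and a few
  remedy pairs are interchangeable alternatives with identical usage laws
  (a signal only relational similarity can see);
* roughly one clinical name in ten has no standard meaning at all.

Tokens default to a reserved block of CJK codepoints so the character
metrics see single-character morphemes, as they do on Chinese; an ASCII
mode exists for readable debugging output.  Generation is fully
deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import (
    Corpus,
    GoldMapping,
    Role,
    SymptomRecord,
    write_gold_mapping,
    write_prescriptions,
)

__all__ = [
    "GeneratorConfig",
    "TokenizedName",
    "SyntheticCorpusBundle",
    "generate_vocabulary",
    "mutate_name",
    "generate_corpus",
    "write_bundle",
]


class GenerationError(RuntimeError):
    """Vocabulary exhausted or configuration unusable."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus, defaulting to the observed proportions
    of real TCM vocabularies (body-part presence ~0.67, standard/clinical
    prefix rates ~0.99/0.80, synonym multiplicity ~0.78, ~10% unmappable
    names) at roughly one-tenth real scale."""

    n_standard: int = 60
    n_remedies: int = 150
    p_bodypart: float = 0.67
    p_prefix_std: float = 0.99
    p_prefix_clin: float = 0.80
    p_multi_synonym: float = 0.78
    p_unnormalizable: float = 0.10
    p_degree: float = 0.5
    p_synonym_sub: float = 0.5
    p_degree_drop: float = 0.3
    signature_size_mean: float = 6.0
    remedy_dropout: float = 0.2
    noise_remedy_rate: float = 0.5
    char_edit_rate: float = 0.05
    n_prescriptions_per_name: int = 5
    n_alternative_pairs: int = 10
    seed: int = 42
    alphabet: str = "cjk"

    def __post_init__(self) -> None:
        for name in (
            "p_bodypart", "p_prefix_std", "p_prefix_clin", "p_multi_synonym",
            "p_unnormalizable", "p_degree", "p_synonym_sub", "p_degree_drop",
            "remedy_dropout", "char_edit_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_standard", "n_remedies", "n_prescriptions_per_name"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_alternative_pairs < 0 or self.signature_size_mean <= 0:
            raise ValueError("n_alternative_pairs >= 0 and signature_size_mean > 0 required")
        if 2 * self.n_alternative_pairs > self.n_remedies:
            raise ValueError("not enough remedies for the requested alternative pairs")
        if self.noise_remedy_rate < 0:
            raise ValueError("noise_remedy_rate must be >= 0")
        if self.alphabet not in ("cjk", "ascii"):
            raise ValueError("alphabet must be 'cjk' or 'ascii'")


@dataclass
class TokenizedName:
    """A symptom name with its token decomposition retained for mutation."""

    tokens: list[tuple[str, str]]  # (kind, text), kind in {body, property, degree}

    @property
    def text(self) -> str:
        return "".join(t for _, t in self.tokens)

    def kinds(self) -> set[str]:
        return {k for k, _ in self.tokens}


@dataclass
class SyntheticCorpusBundle:
    corpus: Corpus
    gold: GoldMapping
    provenance: GeneratorConfig


@dataclass(frozen=True)
class _Inventories:
    body: tuple[str, ...]
    prop: tuple[str, ...]
    degree: tuple[str, ...]
    synonyms: dict[str, str]  # token -> alternative spelling
    noise_chars: tuple[str, ...]


def _char_pool(base: int, count: int) -> list[str]:
    return [chr(base + i) for i in range(count)]


def _make_tokens(pool: Sequence[str], n_single: int, n_double: int) -> tuple[str, ...]:
    singles = list(pool[:n_single])
    doubles = [pool[n_single + 2 * i] + pool[n_single + 2 * i + 1] for i in range(n_double)]
    return tuple(singles + doubles)


@lru_cache(maxsize=4)
def _build_inventories(alphabet: str) -> _Inventories:
    if alphabet == "cjk":
        body_pool = _char_pool(0x4E00, 64)
        prop_pool = _char_pool(0x4F00, 80)
        degree_pool = _char_pool(0x5000, 24)
        syn_pool = _char_pool(0x5100, 160)
        noise_pool = _char_pool(0x5200, 40)
    else:
        body_pool = [chr(ord("A") + i) for i in range(26)] + [chr(ord("a") + i) for i in range(26)] + list("0123456789ÀÁ")
        prop_pool = [chr(0x0391 + i) for i in range(24)] + [chr(0x03B1 + i) for i in range(24)] + [chr(0x0400 + i) for i in range(32)]
        degree_pool = [chr(0x0531 + i) for i in range(24)]
        syn_pool = [chr(0x05D0 + i) for i in range(26)] + [chr(0x0620 + i) for i in range(40)] + [chr(0x0900 + i) for i in range(94)]
        noise_pool = [chr(0x0E01 + i) for i in range(40)]
    body = _make_tokens(body_pool, 16, 20)
    prop = _make_tokens(prop_pool, 20, 24)
    degree = _make_tokens(degree_pool, 8, 6)
    # One alternative spelling per body/property token, same length, drawn
    # deterministically from a disjoint pool: the synonym table.
    synonyms: dict[str, str] = {}
    cursor = 0
    for token in body + prop:
        synonyms[token] = "".join(syn_pool[cursor + i] for i in range(len(token)))
        cursor += len(token)
    return _Inventories(body=body, prop=prop, degree=degree,
                        synonyms=synonyms, noise_chars=tuple(noise_pool))


def generate_vocabulary(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> list[TokenizedName]:
    """Draw ``cfg.n_standard`` unique tokenized standard names.

    Each name holds a disease-property token, optionally a body-part token
    (prefix or interior per the configured probabilities) and optionally a
    degree token.
    """
    inv = _build_inventories(cfg.alphabet)
    names: list[TokenizedName] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * cfg.n_standard
    while len(names) < cfg.n_standard:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                "could not generate enough unique standard names; "
                "token inventories too small for n_standard"
            )
        tokens: list[tuple[str, str]] = [("property", inv.prop[rng.integers(len(inv.prop))])]
        if rng.random() < cfg.p_bodypart:
            body = ("body", inv.body[rng.integers(len(inv.body))])
            if rng.random() < cfg.p_prefix_std:
                tokens.insert(0, body)
            else:
                tokens.append(body)
        if rng.random() < cfg.p_degree:
            tokens.append(("degree", inv.degree[rng.integers(len(inv.degree))]))
        candidate = TokenizedName(tokens=tokens)
        if candidate.text not in seen:
            seen.add(candidate.text)
            names.append(candidate)
    return names


def mutate_name(
    name: TokenizedName, cfg: GeneratorConfig, rng: np.random.Generator
) -> str:
    """Derive a clinical variant spelling from a tokenized standard name.

    Applies, each with its configured probability: synonym substitution of
    one body/property token, relocation of a prefix body part into the
    interior, deletion of the degree token, and independent per-character
    edits.  With all probabilities zero the name is returned unchanged.
    """
    inv = _build_inventories(cfg.alphabet)
    tokens = list(name.tokens)
    # Synonym substitution on one substitutable token.
    if rng.random() < cfg.p_synonym_sub:
        candidates = [i for i, (k, t) in enumerate(tokens) if t in inv.synonyms]
        if candidates:
            i = candidates[rng.integers(len(candidates))]
            kind, tok = tokens[i]
            tokens[i] = (kind, inv.synonyms[tok])
    # Body-part relocation: the clinical prefix rate is the standard rate
    # times the keep probability, so relocate with 1 - p_clin/p_std.
    if tokens and tokens[0][0] == "body" and len(tokens) > 1:
        keep = min(cfg.p_prefix_clin / cfg.p_prefix_std, 1.0) if cfg.p_prefix_std > 0 else 0.0
        if rng.random() >= keep:
            body = tokens.pop(0)
            tokens.insert(1 if len(tokens) >= 1 else 0, body)
    # Degree omission.
    if rng.random() < cfg.p_degree_drop:
        tokens = [t for t in tokens if t[0] != "degree"] or tokens
    text = "".join(t for _, t in tokens)
    if cfg.char_edit_rate > 0:
        chars = list(text)
        for i in range(len(chars)):
            if rng.random() < cfg.char_edit_rate:
                chars[i] = inv.noise_chars[rng.integers(len(inv.noise_chars))]
        text = "".join(chars)
    return text


def _sample_prescription(
    signature: Sequence[str],
    partner: dict[str, str],
    all_remedies: Sequence[str],
    outside: Sequence[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> list[str]:
    kept = [r for r in signature if rng.random() >= cfg.remedy_dropout]
    if not kept:
        kept = [signature[rng.integers(len(signature))]]
    # Alternative remedies are interchangeable: either member of a pair is
    # dispensed with equal probability wherever the signature calls for one.
    emitted = [
        partner[r] if r in partner and rng.random() < 0.5 else r
        for r in kept
    ]
    n_noise = rng.poisson(cfg.noise_remedy_rate)
    for _ in range(n_noise):
        if outside:
            emitted.append(outside[rng.integers(len(outside))])
    return emitted


def generate_corpus(cfg: GeneratorConfig) -> SyntheticCorpusBundle:
    """Generate a full synthetic bundle: corpus, gold mapping, provenance."""
    rng = np.random.default_rng(cfg.seed)
    inv = _build_inventories(cfg.alphabet)
    vocabulary = generate_vocabulary(cfg, rng)
    remedies = [f"r{i:03d}" for i in range(cfg.n_remedies)]

    # Interchangeable remedy pairs with identical usage distributions.
    pair_ids = rng.choice(cfg.n_remedies, size=2 * cfg.n_alternative_pairs, replace=False)
    partner: dict[str, str] = {}
    for a, b in zip(pair_ids[::2], pair_ids[1::2]):
        partner[remedies[a]] = remedies[b]
        partner[remedies[b]] = remedies[a]

    signatures: dict[str, list[str]] = {}
    for name in vocabulary:
        size = max(2, int(rng.poisson(cfg.signature_size_mean)))
        size = min(size, cfg.n_remedies)
        idx = rng.choice(cfg.n_remedies, size=size, replace=False)
        signatures[name.text] = [remedies[i] for i in sorted(idx)]

    records: list[SymptomRecord] = []
    for name in vocabulary:
        sig = signatures[name.text]
        outside = [r for r in remedies if r not in sig]
        prescriptions = [
            _sample_prescription(sig, partner, remedies, outside, cfg, rng)
            for _ in range(cfg.n_prescriptions_per_name)
        ]
        records.append(SymptomRecord(name=name.text, role=Role.STANDARD,
                                     prescriptions=prescriptions))

    gold_pairs: dict[str, str | None] = {}
    clinical_names: set[str] = set()
    n_variants = 0
    for name in vocabulary:
        if rng.random() < cfg.p_multi_synonym:
            n_var = 3 if rng.random() < 0.3 else 2
        else:
            n_var = 1
        sig = signatures[name.text]
        outside = [r for r in remedies if r not in sig]
        for _ in range(n_var):
            variant = mutate_name(name, cfg, rng)
            tries = 0
            while variant in clinical_names and tries < 50:
                variant = mutate_name(name, cfg, rng)
                tries += 1
            if variant in clinical_names:
                # Disambiguate deterministically rather than discard.
                variant = variant + inv.noise_chars[rng.integers(len(inv.noise_chars))]
                if variant in clinical_names:
                    continue
            clinical_names.add(variant)
            gold_pairs[variant] = name.text
            n_variants += 1
            prescriptions = [
                _sample_prescription(sig, partner, remedies, outside, cfg, rng)
                for _ in range(cfg.n_prescriptions_per_name)
            ]
            records.append(SymptomRecord(name=variant, role=Role.CLINICAL,
                                         prescriptions=prescriptions))

    # Unmappable clinical names: junk token strings with arbitrary remedies.
    standard_names = {n.text for n in vocabulary}
    if cfg.p_unnormalizable < 1.0:
        n_none = round(n_variants * cfg.p_unnormalizable / (1.0 - cfg.p_unnormalizable))
    else:
        raise ValueError("p_unnormalizable must be < 1")
    made = 0
    attempts = 0
    while made < n_none and attempts < 200 * max(n_none, 1):
        attempts += 1
        length = 2 + int(rng.integers(3))
        junk = "".join(inv.noise_chars[rng.integers(len(inv.noise_chars))] for _ in range(length))
        if junk in clinical_names or junk in standard_names:
            continue
        clinical_names.add(junk)
        gold_pairs[junk] = None
        size = max(1, int(rng.poisson(cfg.signature_size_mean)))
        size = min(size, cfg.n_remedies)
        idx = rng.choice(cfg.n_remedies, size=size, replace=False)
        junk_sig = [remedies[i] for i in sorted(idx)]
        outside = [r for r in remedies if r not in junk_sig]
        prescriptions = [
            _sample_prescription(junk_sig, partner, remedies, outside, cfg, rng)
            for _ in range(cfg.n_prescriptions_per_name)
        ]
        records.append(SymptomRecord(name=junk, role=Role.CLINICAL,
                                     prescriptions=prescriptions))
        made += 1

    corpus = Corpus(records=records)
    gold = GoldMapping(pairs=gold_pairs)
    return SyntheticCorpusBundle(corpus=corpus, gold=gold, provenance=cfg)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_bundle(bundle: SyntheticCorpusBundle, outdir: str | Path) -> None:
    """Write prescriptions.tsv, gold.tsv and config-echo.toml to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_prescriptions(bundle.corpus, outdir / "prescriptions.tsv")
    write_gold_mapping(bundle.gold, outdir / "gold.tsv")
    lines = ["[generator]"]
    for key, value in asdict(bundle.provenance).items():
        lines.append(f"{key} = {_toml_value(value)}")
    (outdir / "config-echo.toml").write_text("\n".join(lines) + "\n", encoding="utf-8")
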