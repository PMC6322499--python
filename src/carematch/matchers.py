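"""The five index tests for calling an address a care-home address.

Binary methods: institution flag, exact concatenated-address match, and
postcode match. Score methods (0-100): a phonetic name/postcode overlap
score ("phonics") and a naive-Bayes word/word-pair log-odds score
("markov"), trained against a known flag per health board.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

from .address import (
    MISSING,
    CanonicalAddress,
    RawAddress,
    canonicalize,
    canonicalize_postcode,
    concatenate,
    normalize_text,
    phonetic_encode,
)
from .registry import EligibilityRules, Registry, eligible_services

__all__ = [
    "AddressRecord",
    "BinaryCall",
    "ScoreCall",
    "PhonicsConfig",
    "MarkovModel",
    "match_flag",
    "match_exact",
    "match_postcode",
    "score_phonics",
    "train_markov",
    "score_markov",
    "load_population",
]

CARE_HOME_FLAG_CODES = frozenset({93, 98})  # residential, nursing


@dataclass(frozen=True)
class AddressRecord:
    """One population address with its optional institution-flag code."""

    record_id: str
    address: RawAddress
    flag_code: int | None = None
    board: str = ""
    sample: str = ""

    @property
    def canonical(self) -> CanonicalAddress:
        return _canonicalize_cached(self.address)


@lru_cache(maxsize=65536)
def _canonicalize_cached(address: RawAddress) -> CanonicalAddress:
    return canonicalize(address)


@dataclass(frozen=True)
class BinaryCall:
    record_id: str
    method: str
    positive: bool
    matched_service: str | None = None

    def __post_init__(self):
        if self.matched_service is not None and not self.positive:
            raise ValueError("matched_service only allowed on positive calls")


@dataclass(frozen=True)
class ScoreCall:
    record_id: str
    method: str
    score: float
    best_service: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"score out of [0,100]: {self.score}")


def match_flag(record: AddressRecord) -> BinaryCall:
    """Positive iff the institution flag carries a care-home code (93/98).

    An absent code is negative, mirroring the treatment of missing
    postcodes: routine data always contains missingness and exclusion
    would change denominators.
    """
    positive = record.flag_code in CARE_HOME_FLAG_CODES
    return BinaryCall(record.record_id, "flag", positive)


def _registry_concatenations(registry: Registry, eligible: set[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for sid in sorted(eligible):
        svc = registry[sid]
        key = concatenate(svc.address)
        out.setdefault(key, sid)  # lowest id wins on ties
    return out


def match_exact(
    record: AddressRecord,
    registry: Registry,
    include_cancelled: bool = True,
    rules: EligibilityRules = EligibilityRules(),
) -> BinaryCall:
    """Positive iff the record's concatenated normalized address equals an
    eligible service's concatenated address character for character."""
    eligible = eligible_services(registry, include_cancelled, rules)
    table = _registry_concatenations(registry, eligible)
    key = concatenate(record.address)
    sid = table.get(key) if key else None
    return BinaryCall(record.record_id, "exact", sid is not None, sid)


def match_postcode(
    record: AddressRecord,
    registry: Registry,
    include_cancelled: bool = True,
    rules: EligibilityRules = EligibilityRules(),
) -> BinaryCall:
    """Positive iff the canonical postcode matches an eligible care-home's
    postcode after removing spaces; MISSING postcodes are negative."""
    pc = record.canonical.postcode
    if pc is MISSING:
        return BinaryCall(record.record_id, "postcode", False)
    eligible = eligible_services(registry, include_cancelled, rules)
    hits = sorted(registry.by_postcode.get(pc, set()) & eligible)
    if hits:
        return BinaryCall(record.record_id, "postcode", True, hits[0])
    return BinaryCall(record.record_id, "postcode", False)


@dataclass(frozen=True)
class PhonicsConfig:
    """Free parameters of the phonetic score."""

    w_postcode: float = 0.25
    w_name: float = 0.75
    quantization_levels: int = 4
    stop_tokens: frozenset[str] = frozenset({"CARE", "HOME", "NURSING", "THE"})
    restrict_to_board: bool = True

    def __post_init__(self):
        if self.w_postcode < 0 or self.w_name < 0:
            raise ValueError("weights must be nonnegative")
        if not math.isclose(self.w_postcode + self.w_name, 1.0):
            raise ValueError("weights must sum to 1")
        if self.quantization_levels < 1:
            raise ValueError("quantization_levels must be >= 1")


def _service_name_tokens(registry: Registry, sid: str, stop: frozenset[str]):
    tokens = [t for t in normalize_text(registry[sid].name).split() if t not in stop]
    return [(t, phonetic_encode(t)) for t in tokens]


def score_phonics(
    record: AddressRecord,
    registry: Registry,
    config: PhonicsConfig = PhonicsConfig(),
    include_cancelled: bool = True,
    rules: EligibilityRules = EligibilityRules(),
) -> ScoreCall:
    """Phonetic overlap score in [0, 100].

    For each candidate eligible service (in the record's board unless
    configured otherwise) the raw score is

        w_postcode * [postcodes equal, both present]
        + w_name * Q(fraction of the service's non-stop name tokens whose
                     metaphone OR soundex code occurs among the record's
                     phonetic codes)

    where Q rounds to the nearest of q+1 equally spaced levels in [0, 1].
    The best candidate's score, scaled to 0-100 and rounded to the nearest
    integer, is reported; ties break to the lowest service id.
    """
    eligible = eligible_services(registry, include_cancelled, rules)
    if config.restrict_to_board:
        eligible = eligible & registry.by_board.get(record.board, set())
    if not eligible:
        return ScoreCall(record.record_id, "phonics", 0.0)

    from .address import SENTINEL_CODES

    canon = record.canonical
    record_codes = set()
    for mp, sx in canon.phonetic_tokens:
        if (mp, sx) == SENTINEL_CODES:
            continue  # numeric tokens carry no phonetic content
        record_codes.add(("m", mp))
        record_codes.add(("s", sx))

    q = config.quantization_levels
    best_score, best_sid = 0.0, None
    for sid in sorted(eligible):
        svc_pc = registry[sid].address.postcode
        pc_match = (
            canon.postcode is not MISSING
            and canonicalize_postcode(svc_pc) is not MISSING
            and canon.postcode == canonicalize_postcode(svc_pc)
        )
        name_tokens = _service_name_tokens(registry, sid, config.stop_tokens)
        if name_tokens:
            hits = sum(
                1
                for _, (mp, sx) in name_tokens
                if ("m", mp) in record_codes or ("s", sx) in record_codes
            )
            frac = hits / len(name_tokens)
        else:
            frac = 0.0
        quantized = round(frac * q) / q
        raw = config.w_postcode * (1.0 if pc_match else 0.0) + config.w_name * quantized
        if raw > best_score:
            best_score, best_sid = raw, sid
    score = float(round(100 * best_score))
    return ScoreCall(record.record_id, "phonics", score, best_sid if score > 0 else None)


@dataclass
class MarkovModel:
    """Per-board naive-Bayes log-likelihood-ratio weights over words and
    adjacent word pairs, trained against a known binary flag."""

    alpha: float
    global_prior_logodds: float
    board_priors: dict[str, float] = field(default_factory=dict)
    unigram_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    bigram_weights: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    vocab_sizes: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "alpha": self.alpha,
            "global_prior_logodds": self.global_prior_logodds,
            "board_priors": self.board_priors,
            "unigram_weights": {
                f"{b}\t{t}": w for (b, t), w in self.unigram_weights.items()
            },
            "bigram_weights": {
                f"{b}\t{t1}\t{t2}": w
                for (b, (t1, t2)), w in self.bigram_weights.items()
            },
            "vocab_sizes": self.vocab_sizes,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MarkovModel":
        doc = json.loads(text)
        uni = {}
        for key, w in doc["unigram_weights"].items():
            b, t = key.split("\t")
            uni[(b, t)] = w
        bi = {}
        for key, w in doc["bigram_weights"].items():
            b, t1, t2 = key.split("\t")
            bi[(b, (t1, t2))] = w
        return cls(
            alpha=doc["alpha"],
            global_prior_logodds=doc["global_prior_logodds"],
            board_priors=doc["board_priors"],
            unigram_weights=uni,
            bigram_weights=bi,
            vocab_sizes=doc["vocab_sizes"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MarkovModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _bigrams(tokens):
    return list(zip(tokens, tokens[1:]))


def _family_weights(pos_feats, neg_feats, alpha):
    """Smoothed log-likelihood-ratio weight per feature.

    weight(f) = log[(c_pos(f)+a) / (m_pos + a*V)] - log[(c_neg(f)+a) / (m_neg + a*V)]
    with V the vocabulary shared across both classes for the family.
    """
    vocab = set(pos_feats) | set(neg_feats)
    v = len(vocab)
    m_pos = sum(pos_feats.values())
    m_neg = sum(neg_feats.values())
    weights = {}
    for f in vocab:
        lp = math.log((pos_feats.get(f, 0) + alpha) / (m_pos + alpha * v))
        ln = math.log((neg_feats.get(f, 0) + alpha) / (m_neg + alpha * v))
        weights[f] = lp - ln
    return weights, v


def train_markov(
    records: list[AddressRecord],
    labels: list[bool],
    alpha: float = 1.0,
) -> MarkovModel:
    """Fit the per-board word / word-pair log-odds model.

    Each health board gets its own weight set (similar care-home names
    recur across regions); a board whose training data is single-class
    contributes a smoothed prior only. Raises ValueError when the pooled
    training labels are single-class.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if len(records) != len(labels):
        raise ValueError("records and labels must align")
    n_pos = sum(bool(y) for y in labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training requires at least one record of each class")

    model = MarkovModel(
        alpha=alpha, global_prior_logodds=math.log(n_pos / n_neg)
    )

    by_board: dict[str, list[tuple[AddressRecord, bool]]] = {}
    for rec, y in zip(records, labels):
        by_board.setdefault(rec.board, []).append((rec, bool(y)))

    for board, pairs in sorted(by_board.items()):
        b_pos = sum(y for _, y in pairs)
        b_neg = len(pairs) - b_pos
        # smoothed prior keeps single-class boards finite
        model.board_priors[board] = math.log((b_pos + alpha) / (b_neg + alpha))
        if b_pos == 0 or b_neg == 0:
            continue
        uni = {True: {}, False: {}}
        bi = {True: {}, False: {}}
        for rec, y in pairs:
            tokens = rec.canonical.tokens
            for t in tokens:
                uni[y][t] = uni[y].get(t, 0) + 1
            for pair in _bigrams(tokens):
                bi[y][pair] = bi[y].get(pair, 0) + 1
        uw, uv = _family_weights(uni[True], uni[False], alpha)
        bw, bv = _family_weights(bi[True], bi[False], alpha)
        for t, w in uw.items():
            model.unigram_weights[(board, t)] = w
        for pair, w in bw.items():
            model.bigram_weights[(board, pair)] = w
        model.vocab_sizes[board] = {"unigram": uv, "bigram": bv}
    return model


def score_markov(model: MarkovModel, record: AddressRecord) -> ScoreCall:
    """0-100 probability score: logistic of prior + summed feature weights.

    Unknown words/pairs (and unknown boards beyond the prior) contribute 0.
    """
    board = record.board
    logodds = model.board_priors.get(board, model.global_prior_logodds)
    tokens = record.canonical.tokens
    for t in tokens:
        logodds += model.unigram_weights.get((board, t), 0.0)
    for pair in _bigrams(tokens):
        logodds += model.bigram_weights.get((board, pair), 0.0)
    prob = 1.0 / (1.0 + math.exp(-logodds))
    return ScoreCall(record.record_id, "markov", round(100.0 * prob, 1))


def load_population(path) -> list[AddressRecord]:
    """Read a population address CSV into AddressRecord objects."""
    from .address import read_address_table  # pandas kept out of import path

    df = read_address_table(path)
    ids = df["record_id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record_id values in population table")
    records = []
    for row in df.itertuples(index=False):
        flag = row.flag_code.strip()
        records.append(
            AddressRecord(
                record_id=row.record_id,
                address=RawAddress(
                    lines=(row.line1, row.line2, row.line3, row.line4, row.line5),
                    postcode=row.postcode,
                ),
                flag_code=int(flag) if flag else None,
                board=row.board,
                sample=row.sample,
            )
        )
    return records
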