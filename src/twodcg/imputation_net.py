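"""Feed-forward ensemble that learns phenotype and pathogenicity from the
four independent 6ddp variables and imputes unknown outcomes.

The causal graph puts domain, pooled residue substitution, population and
allele-frequency category upstream of the two outcomes, so the features are
a concatenation of one-hot blocks for (cd, re, po, af) and each outcome gets
its own classifier head (the heads are independent).  A pool of candidate
two-head models is trained from distinct random initializations on the
fulfilled records; the 20 with the highest *exact reproduction* — both heads
simultaneously correct on a held-out stratified split — form the ensemble
("best of the best").  Models are expected to exactly reproduce at least
60% of the known records; imputation replaces each unknown outcome by the
ensemble's plurality vote.

scikit-learn's MLPClassifier does the fitting; predictions run through an
in-package forward pass over the extracted weights so that models serialized
to the portable text bundle predict identically after reload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from .vocab_io import (
    PATHOGENICITY_CODES,
    POOLED_CLASSES,
    UNKNOWN_PATHOGENICITY,
    UNKNOWN_PHENOTYPE,
    CodeVocabulary,
    DomainVocabulary,
    SixDDPDataset,
    SixDDPRecord,
    VocabularyError,
)

__all__ = [
    "EnsembleConfig",
    "Encoder",
    "TwoHeadModel",
    "ModelEnsemble",
    "TrainingError",
    "encode_record",
    "train_ensemble",
    "impute",
    "save_ensemble",
    "load_ensemble",
]

#: all ordered pooled ref/sub class pairs, the ``re`` one-hot alphabet
RE_PAIRS: tuple[tuple[str, str], ...] = tuple(product(POOLED_CLASSES, POOLED_CLASSES))


class TrainingError(RuntimeError):
    """No candidate model reached the configured exact-reproduction floor."""


@dataclass(frozen=True)
class EnsembleConfig:
    """Training knobs.

    ``hidden_width=None`` means "equal to the feature dimension".  The pool
    trains ``pool_size`` candidates and keeps the best ``ensemble_size``;
    ``floor`` is the minimum acceptable exact-reproduction fraction for the
    best model.
    """

    hidden_width: Optional[int] = None
    pool_size: int = 100
    ensemble_size: int = 20
    floor: float = 0.60
    val_fraction: float = 0.20
    activation: str = "logistic"
    max_iter: int = 300
    alpha: float = 1e-4
    learning_rate_init: float = 0.001


@dataclass(frozen=True)
class Encoder:
    """Deterministic one-hot encoding of the four independent variables."""

    domains: DomainVocabulary
    populations: CodeVocabulary
    phenotypes: CodeVocabulary

    @property
    def feature_names(self) -> tuple[str, ...]:
        return (
            tuple(f"cd:{c}" for c in self.domains.codes)
            + tuple(f"re:{r}>{s}" for r, s in RE_PAIRS)
            + tuple(f"po:{c}" for c in self.populations.codes)
            + ("af:0", "af:1")
        )

    @property
    def n_features(self) -> int:
        return len(self.domains) + len(RE_PAIRS) + len(self.populations) + 2

    @property
    def ph_classes(self) -> tuple[str, ...]:
        return self.phenotypes.codes

    @property
    def pa_classes(self) -> tuple[str, ...]:
        return tuple(c for c in PATHOGENICITY_CODES if c != UNKNOWN_PATHOGENICITY)

    def encode(self, record: SixDDPRecord) -> np.ndarray:
        vec = np.zeros(self.n_features)
        off = 0
        vec[off + self.domains.index_of(record.cd) - 1] = 1.0
        off += len(self.domains)
        try:
            vec[off + RE_PAIRS.index((record.re.ref_class, record.re.sub_class))] = 1.0
        except ValueError:
            raise VocabularyError(f"unpooled residue pair {record.re}") from None
        off += len(RE_PAIRS)
        po_codes = self.populations.codes
        try:
            vec[off + po_codes.index(record.po)] = 1.0
        except ValueError:
            raise VocabularyError(f"unknown population {record.po!r}") from None
        off += len(po_codes)
        vec[off + record.af] = 1.0
        return vec

    def decode(self, vec: np.ndarray) -> tuple[str, tuple[str, str], str, int]:
        """Inverse of :meth:`encode` on the independent fields."""
        off = 0
        cd = self.domains.codes[int(np.argmax(vec[off:off + len(self.domains)]))]
        off += len(self.domains)
        re_pair = RE_PAIRS[int(np.argmax(vec[off:off + len(RE_PAIRS)]))]
        off += len(RE_PAIRS)
        po = self.populations.codes[
            int(np.argmax(vec[off:off + len(self.populations)]))
        ]
        off += len(self.populations)
        af = int(np.argmax(vec[off:off + 2]))
        return cd, re_pair, po, af

    def matrix(self, dataset: SixDDPDataset) -> np.ndarray:
        return np.array([self.encode(r) for r in dataset.records])


def encode_record(record: SixDDPRecord, encoder: Encoder) -> np.ndarray:
    return encoder.encode(record)


# ---------------------------------------------------------------------------
# Two-head model with a portable forward pass
# ---------------------------------------------------------------------------

def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "tanh":
        return np.tanh(z)
    if kind == "relu":
        return np.maximum(z, 0.0)
    raise ValueError(f"unsupported activation {kind!r}")


@dataclass
class _Head:
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    classes: tuple[str, ...]
    activation: str

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = X
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            z = _activate(z @ W + b, self.activation)
        logits = z @ self.coefs[-1] + self.intercepts[-1]
        if logits.shape[1] == 1:  # binary head: single sigmoid unit
            pos = (logits[:, 0] > 0).astype(int)
            return np.asarray(self.classes)[pos]
        return np.asarray(self.classes)[np.argmax(logits, axis=1)]

    @classmethod
    def from_sklearn(cls, clf: MLPClassifier, activation: str) -> "_Head":
        return cls(
            coefs=[np.asarray(W) for W in clf.coefs_],
            intercepts=[np.asarray(b) for b in clf.intercepts_],
            classes=tuple(str(c) for c in clf.classes_),
            activation=activation,
        )


@dataclass
class TwoHeadModel:
    ph_head: _Head
    pa_head: _Head
    seed: int
    score: float = float("nan")

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.ph_head.predict(X), self.pa_head.predict(X)

    def exact_reproduction(
        self, X: np.ndarray, y_ph: np.ndarray, y_pa: np.ndarray
    ) -> float:
        ph, pa = self.predict(X)
        return float(np.mean((ph == y_ph) & (pa == y_pa)))


@dataclass
class ModelEnsemble:
    models: list[TwoHeadModel]
    encoder: Encoder
    config: EnsembleConfig
    seed: int

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(m.score for m in self.models)


def _stratified_split(
    labels: Sequence[tuple[str, str]], val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(ph, pa)-class shuffle split; singleton classes stay in training."""
    groups: dict[tuple[str, str], list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    train, val = [], []
    for lab in sorted(groups):
        idx = np.array(groups[lab])
        rng.shuffle(idx)
        n_val = int(round(val_fraction * len(idx)))
        n_val = min(n_val, len(idx) - 1)  # keep >=1 per class in training
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.array(sorted(train)), np.array(sorted(val))


def train_ensemble(
    fulfilled: SixDDPDataset,
    encoder: Encoder,
    config: EnsembleConfig = EnsembleConfig(),
    seed: int = 0,
) -> ModelEnsemble:
    """Train the candidate pool and keep the best-of-the-best ensemble.

    Candidate score = fraction of held-out fulfilled records with both heads
    simultaneously correct.  Fully reproducible given ``seed``.  Raises
    :class:`TrainingError` when even the best candidate misses the floor.
    """
    if len(fulfilled) == 0 or not all(fulfilled.fulfilled_mask):
        raise ValueError("training data must be non-empty and fully fulfilled")
    if config.ensemble_size > config.pool_size:
        raise ValueError("pool_size must be >= ensemble_size")

    X = encoder.matrix(fulfilled)
    y_ph = np.array([r.ph for r in fulfilled.records])
    y_pa = np.array([r.pa for r in fulfilled.records])
    rng = np.random.default_rng(seed)
    train_idx, val_idx = _stratified_split(
        list(zip(y_ph, y_pa)), config.val_fraction, rng
    )
    if len(val_idx) == 0:  # degenerate tiny data: validate on training set
        val_idx = train_idx
    width = config.hidden_width or encoder.n_features
    cand_seeds = rng.integers(0, 2**31 - 1, size=config.pool_size)

    candidates: list[TwoHeadModel] = []
    for cand_seed in cand_seeds:
        heads = []
        for y in (y_ph, y_pa):
            clf = MLPClassifier(
                hidden_layer_sizes=(width,),
                activation=config.activation,
                alpha=config.alpha,
                max_iter=config.max_iter,
                learning_rate_init=config.learning_rate_init,
                random_state=int(cand_seed) % (2**31 - 1),
                solver="adam",
            )
            if len(np.unique(y[train_idx])) == 1:
                # constant outcome: a trivial head
                heads.append(
                    _Head(
                        coefs=[np.zeros((X.shape[1], 1)), np.zeros((1, 1))],
                        intercepts=[np.zeros(1), np.ones(1)],
                        classes=(str(y[train_idx][0]), str(y[train_idx][0])),
                        activation=config.activation,
                    )
                )
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence warnings expected
                clf.fit(X[train_idx], y[train_idx])
            heads.append(_Head.from_sklearn(clf, config.activation))
        model = TwoHeadModel(ph_head=heads[0], pa_head=heads[1], seed=int(cand_seed))
        model.score = model.exact_reproduction(X[val_idx], y_ph[val_idx], y_pa[val_idx])
        candidates.append(model)

    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].score, i))
    best = [candidates[i] for i in order[: config.ensemble_size]]
    if best[0].score < config.floor:
        raise TrainingError(
            f"best exact-reproduction {best[0].score:.3f} below floor "
            f"{config.floor:.2f} (pool of {config.pool_size})"
        )
    return ModelEnsemble(models=best, encoder=encoder, config=config, seed=seed)


def _plurality(votes: np.ndarray, class_order: Sequence[str]) -> str:
    """Most-voted class; ties resolve to the lowest class index."""
    counts = {c: 0 for c in class_order}
    for v in votes:
        counts[str(v)] = counts.get(str(v), 0) + 1
    return max(class_order, key=lambda c: (counts.get(c, 0), -class_order.index(c)))


def impute(ensemble: ModelEnsemble, dataset: SixDDPDataset) -> SixDDPDataset:
    """Replace unknown ph/pa outcomes by ensemble plurality vote.

    Independent fields and already-known outcomes are never altered; the
    returned dataset is fully fulfilled.
    """
    enc = ensemble.encoder
    todo = [i for i, r in enumerate(dataset.records) if not r.fulfilled]
    if not todo:
        return SixDDPDataset(list(dataset.records), provenance=dataset.provenance)

    X = np.array([enc.encode(dataset.records[i]) for i in todo])
    ph_votes = np.stack([m.ph_head.predict(X) for m in ensemble.models])
    pa_votes = np.stack([m.pa_head.predict(X) for m in ensemble.models])

    ph_order = list(enc.ph_classes)
    pa_order = list(enc.pa_classes)
    records = list(dataset.records)
    for col, i in enumerate(todo):
        r = records[i]
        ph = r.ph if r.ph != UNKNOWN_PHENOTYPE else _plurality(ph_votes[:, col], ph_order)
        pa = r.pa if r.pa != UNKNOWN_PATHOGENICITY else _plurality(pa_votes[:, col], pa_order)
        records[i] = SixDDPRecord(cd=r.cd, re=r.re, po=r.po, af=r.af, ph=ph, pa=pa)
    return SixDDPDataset(records, provenance=dataset.provenance)


# ---------------------------------------------------------------------------
# Portable text serialization
# ---------------------------------------------------------------------------

def _write_head(head: _Head, prefix: Path) -> dict:
    meta = {"classes": list(head.classes), "activation": head.activation,
            "layers": []}
    for li, (W, b) in enumerate(zip(head.coefs, head.intercepts)):
        wpath = prefix.with_name(prefix.name + f"_w{li}.tsv")
        bpath = prefix.with_name(prefix.name + f"_b{li}.tsv")
        np.savetxt(wpath, W, delimiter="\t")
        np.savetxt(bpath, np.atleast_1d(b), delimiter="\t")
        meta["layers"].append({"weights": wpath.name, "bias": bpath.name})
    return meta


def _read_head(meta: dict, directory: Path) -> _Head:
    coefs, intercepts = [], []
    for layer in meta["layers"]:
        W = np.loadtxt(directory / layer["weights"], delimiter="\t", ndmin=2)
        b = np.loadtxt(directory / layer["bias"], delimiter="\t", ndmin=1)
        coefs.append(W)
        intercepts.append(b)
    return _Head(coefs, intercepts, tuple(meta["classes"]), meta["activation"])


def save_ensemble(ensemble: ModelEnsemble, directory: str | Path) -> None:
    """Write the bundle: manifest JSON plus per-layer TSV weight matrices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": ensemble.seed,
        "config": ensemble.config.__dict__,
        "architecture": (
            f"one-hot[{ensemble.encoder.n_features}] -> "
            f"dense[{ensemble.config.hidden_width or ensemble.encoder.n_features}] "
            f"({ensemble.config.activation}) -> two softmax heads (ph, pa)"
        ),
        "models": [],
    }
    for mi, m in enumerate(ensemble.models):
        entry = {
            "seed": m.seed,
            "score": m.score,
            "ph": _write_head(m.ph_head, directory / f"model{mi:02d}_ph"),
            "pa": _write_head(m.pa_head, directory / f"model{mi:02d}_pa"),
        }
        manifest["models"].append(entry)
    (directory / "ensemble.json").write_text(json.dumps(manifest, indent=1))


def load_ensemble(directory: str | Path, encoder: Encoder) -> ModelEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "ensemble.json").read_text())
    config = EnsembleConfig(**manifest["config"])
    models = []
    for entry in manifest["models"]:
        m = TwoHeadModel(
            ph_head=_read_head(entry["ph"], directory),
            pa_head=_read_head(entry["pa"], directory),
            seed=int(entry["seed"]),
            score=float(entry["score"]),
        )
        models.append(m)
    return ModelEnsemble(models=models, encoder=encoder, config=config,
                         seed=int(manifest["seed"]))
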