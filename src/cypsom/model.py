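"""Site classifier: pooled directed-MPNN encoder + per-isoform XGBoost.

Training protocol
-----------------
The encoder is the shared feature generator: it is trained with the weighted
cross-entropy loss on (molecule, isoform) instances pooled across isoforms —
the target isoform contributes only its training-split molecules, every other
isoform contributes all of its molecules.  Metabolic behaviour overlaps
between isoforms, so pooling regularises the encoder; the light noise it adds
is the price of generalisation.  After each encoder epoch the *real*
discriminator — an XGBoost booster with a binary-logistic objective evaluated
by Jaccard score — is retrained from scratch on the target isoform's site
embeddings, and the epoch whose booster scores the best validation Jaccard is
retained.

Operating modes
---------------
``precision`` leaves XGBoost's ``scale_pos_weight`` at its default (1), giving
fewer but surer SOM calls; ``recall`` raises the positive-class weight to
``c * n_neg / n_pos`` so that calls become more complete at some cost in
precision.  (``weight_formula="pos_over_neg"`` exposes the inverted ratio
``c * n_pos / n_neg`` for completeness; see docs/methods.md.)

Predicted SOMs are the sites whose booster probability exceeds 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin

from . import encoder as enc
from . import featurize
from .chem import ISOFORMS, MoleculeRecord, SiteKey, label_soms, split_by_molecule
from .errors import ConfigError, DataError
from .metrics import confusion_from_calls, site_metrics

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Booster configuration and positive-class weighting
# ---------------------------------------------------------------------------

@dataclass
class BoosterConfig:
    """Per-isoform XGBoost tunables.  Objective is fixed to binary logistic
    and the evaluation function to Jaccard score."""

    n_estimators: int = 100
    reg_lambda: float = 1.0
    max_depth: int = 6
    colsample_bytree: float = 1.0
    scale_pos_weight: float | str = "default"

    def __post_init__(self) -> None:
        if min(self.n_estimators, self.max_depth) <= 0:
            raise ConfigError("booster tunables must be positive")
        if self.reg_lambda < 0 or not 0 < self.colsample_bytree <= 1:
            raise ConfigError("invalid booster tunables")


def pos_weight(
    mode: str,
    n_pos: int,
    n_neg: int,
    c: float = 1.0,
    weight_formula: str = "neg_over_pos",
) -> float:
    """scale_pos_weight for the requested operating mode.

    Precision mode keeps the implementation default (1).  Recall mode scales
    the positive class by ``c * n_neg / n_pos`` under the conventional
    orientation (default); ``weight_formula="pos_over_neg"`` gives the
    inverted ratio ``c * n_pos / n_neg``.
    """
    if mode == "precision":
        return 1.0
    if mode != "recall":
        raise ConfigError(f"unknown mode {mode!r}")
    if n_neg <= 0 or n_pos <= 0:
        raise DataError("recall-mode weighting needs both classes present")
    if weight_formula == "neg_over_pos":
        return c * n_neg / n_pos
    if weight_formula == "pos_over_neg":
        return c * n_pos / n_neg
    raise ConfigError(f"unknown weight_formula {weight_formula!r}")


def fit_epoch_booster(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: BoosterConfig,
    seed: int = 0,
    isoform: str = "?",
):
    """Train one booster on the current epoch's embeddings.

    Returns (booster, metric block) where the block carries Jaccard,
    precision, recall and F1 on the train and validation splits at the 0.5
    call threshold.
    """
    if len(np.unique(y_train)) < 2:
        raise DataError(f"isoform {isoform}: single-class training labels")
    spw = 1.0 if cfg.scale_pos_weight == "default" else float(cfg.scale_pos_weight)
    booster = xgb.XGBClassifier(
        n_estimators=cfg.n_estimators,
        reg_lambda=cfg.reg_lambda,
        max_depth=cfg.max_depth,
        colsample_bytree=cfg.colsample_bytree,
        objective="binary:logistic",
        scale_pos_weight=spw,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    booster.fit(X_train, y_train)
    block = {}
    for split, X, y in (("train", X_train, y_train), ("val", X_val, y_val)):
        calls = booster.predict_proba(X)[:, 1] > 0.5
        m = site_metrics(confusion_from_calls(y, calls))
        block.update({f"{split}_{k}": v for k, v in m.items()})
    return booster, block


# ---------------------------------------------------------------------------
# Prediction report
# ---------------------------------------------------------------------------

@dataclass
class PredictionReport:
    """Per-site probabilities and thresholded SOM calls for a batch."""

    isoform: str
    frame: pd.DataFrame           # mol_id, site_kind, atoms, probability, called
    errors: list[tuple[str, str]]

    def called_sites(self, mol_id: str) -> list[SiteKey]:
        sub = self.frame[(self.frame.mol_id == mol_id) & self.frame.called]
        out = []
        for _, row in sub.iterrows():
            atoms = [int(a) for a in str(row.atoms).split("-")]
            if row.site_kind == "bond":
                out.append(SiteKey.bond(*atoms))
            elif row.site_kind == "atom":
                out.append(SiteKey.atom(atoms[0]))
            else:
                out.append(SiteKey.hbond(atoms[0]))
        return out


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class SitePredictor(ClassifierMixin, BaseEstimator):
    """Site-of-metabolism classifier for one CYP450 isoform.

    Parameters
    ----------
    target_isoform : str
        One of the nine isoform names.
    mode : {"precision", "recall"}
        Operating mode; only changes the booster's positive-class weight.
    c : float
        Recall-mode weight multiplier.
    weight_formula : {"neg_over_pos", "pos_over_neg"}
        Orientation of the recall-mode class-weight ratio.
    loss_a, loss_b : float
        Importance of positive-site and negative-site encoder loss.
    hidden_size, depth, dropout, activation, learning_rate, epochs
        Encoder hyperparameters (width of hidden states, message-passing
        rounds, dropout rate, "leaky_relu" or "relu", Adam step size, number
        of encoder epochs).
    batch_size : int
        Molecules per encoder minibatch.
    mol_features : {"none", "fixed", "encoder"}
        Whole-molecule feature source concatenated to every site embedding:
        none, the six fixed-rule descriptors (z-scored on the training set),
        or a second, independently trained directed-MPNN.
    mol_hidden_size, mol_depth, mol_out_dim, mol_pooling
        Second-encoder hyperparameters (used when mol_features="encoder").
    booster : BoosterConfig or None
        XGBoost tunables (None = defaults).
    val_fraction : float
        Molecule-level validation fraction of the target isoform's data.
    booster_every : int
        Retrain the booster every k encoder epochs (1 = the full protocol;
        the final epoch is always scored).
    random_state : int
        Master seed; fans out to split, init, dropout and booster.
    """

    def __init__(
        self,
        target_isoform: str = "3A4",
        mode: str = "precision",
        c: float = 1.0,
        weight_formula: str = "neg_over_pos",
        loss_a: float = 1.0,
        loss_b: float = 1.0,
        hidden_size: int = 300,
        depth: int = 3,
        dropout: float = 0.05,
        activation: str = "leaky_relu",
        learning_rate: float = 1e-3,
        epochs: int = 30,
        batch_size: int = 8,
        mol_features: str = "none",
        mol_hidden_size: int = 64,
        mol_depth: int = 2,
        mol_out_dim: int = 32,
        mol_pooling: str = "sum",
        booster: BoosterConfig | None = None,
        val_fraction: float = 0.2,
        booster_every: int = 1,
        random_state: int = 0,
    ):
        self.target_isoform = target_isoform
        self.mode = mode
        self.c = c
        self.weight_formula = weight_formula
        self.loss_a = loss_a
        self.loss_b = loss_b
        self.hidden_size = hidden_size
        self.depth = depth
        self.dropout = dropout
        self.activation = activation
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.mol_features = mol_features
        self.mol_hidden_size = mol_hidden_size
        self.mol_depth = mol_depth
        self.mol_out_dim = mol_out_dim
        self.mol_pooling = mol_pooling
        self.booster = booster
        self.val_fraction = val_fraction
        self.booster_every = booster_every
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _graph(self, rec: MoleculeRecord) -> enc.MolGraph:
        g = self._graph_cache.get(rec.mol_id)
        if g is None:
            g = enc.build_graph(rec)
            self._graph_cache[rec.mol_id] = g
        return g

    def _mol_part(self, batch: enc.BatchedGraph, records_by_id, training, rng):
        """Per-molecule feature block broadcast to sites, plus cache."""
        if self.mol_features == "none":
            return None, None
        if self.mol_features == "fixed":
            rows = np.vstack(
                [self._fixed_desc(records_by_id[mid]) for mid in batch.mol_ids]
            )
            return rows, None
        molvecs, cache = enc.molecule_embedding(
            batch, self.mol_encoder_params_, training=training, rng=rng
        )
        return molvecs, cache

    def _fixed_desc(self, rec: MoleculeRecord) -> np.ndarray:
        raw = featurize.molecular_descriptors(rec.mol)
        return (raw - self.mol_feat_mean_) / self.mol_feat_std_

    def _forward(self, batch, records_by_id, training, rng):
        F, cache = enc.encode_sites(batch, self.encoder_params_, training, rng)
        mol_rows, mol_cache = self._mol_part(batch, records_by_id, training, rng)
        if mol_rows is not None:
            F_full = np.hstack([F, mol_rows[batch.site_mol]])
        else:
            F_full = F
        probs = enc.probability_head(F_full, self.head_params_)
        return probs, F_full, {"site": cache, "mol": mol_cache, "F_dim": F.shape[1]}

    def _embeddings(self, records: Sequence[MoleculeRecord]) -> tuple[np.ndarray, enc.BatchedGraph]:
        """Eval-mode site embeddings (booster input) for a list of records."""
        batch = enc.batch_graphs([self._graph(r) for r in records])
        records_by_id = {r.mol_id: r for r in records}
        F, _ = enc.encode_sites(batch, self.encoder_params_, training=False)
        mol_rows, _ = self._mol_part(batch, records_by_id, training=False, rng=None)
        if mol_rows is not None:
            F = np.hstack([F, mol_rows[batch.site_mol]])
        return F, batch

    # -- fitting ----------------------------------------------------------

    def fit(self, X: Sequence[MoleculeRecord], y=None) -> "SitePredictor":
        """Fit on a list of annotated :class:`MoleculeRecord` objects.

        ``y`` is ignored: labels are derived from the records' BOM
        annotations for each isoform.
        """
        records = list(X)
        if self.target_isoform not in ISOFORMS:
            raise ConfigError(f"unknown isoform {self.target_isoform!r}")
        if self.mode not in ("precision", "recall"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        labeled = {
            iso: {r.mol_id: label_soms(r, iso) for r in records}
            for iso in ISOFORMS
        }
        target = self.target_isoform
        target_records = [
            r for r in records if labeled[target][r.mol_id].n_positive > 0
        ]
        if len(target_records) < 2:
            raise DataError(
                f"isoform {target} has fewer than 2 annotated molecules"
            )

        master = np.random.SeedSequence(self.random_state)
        s_split, s_init, s_drop, s_boost, s_shuffle = master.spawn(5)
        split_seed = int(s_split.generate_state(1)[0] % (2**31))
        booster_seed = int(s_boost.generate_state(1)[0] % (2**31))
        rng_init = np.random.default_rng(s_init)
        rng_drop = np.random.default_rng(s_drop)
        rng_shuffle = np.random.default_rng(s_shuffle)

        self.split_ = split_by_molecule(
            target_records, 1.0 - self.val_fraction, split_seed
        )
        by_id = {r.mol_id: r for r in records}
        train_recs = [by_id[i] for i in self.split_.train_ids]
        val_recs = [by_id[i] for i in self.split_.val_ids]

        # pooled encoder instances: (record, isoform) pairs
        pool_isoforms = [
            iso for iso in ISOFORMS
            if any(ls.n_positive > 0 for ls in labeled[iso].values())
        ]
        instances: list[tuple[MoleculeRecord, str]] = []
        for iso in pool_isoforms:
            mols = train_recs if iso == target else records
            instances.extend((r, iso) for r in mols)

        self._graph_cache: dict[str, enc.MolGraph] = {}
        self.encoder_params_ = enc.init_encoder_params(
            self.hidden_size, self.depth, self.dropout, self.activation,
            rng=rng_init,
        )
        head_in = self.hidden_size
        if self.mol_features == "fixed":
            desc = np.vstack([featurize.molecular_descriptors(r.mol) for r in records])
            self.mol_feat_mean_ = desc.mean(axis=0)
            self.mol_feat_std_ = np.where(desc.std(axis=0) > 0, desc.std(axis=0), 1.0)
            head_in += featurize.MOL_FDIM
        elif self.mol_features == "encoder":
            self.mol_encoder_params_ = enc.init_molecule_encoder_params(
                self.mol_hidden_size, self.mol_depth, self.mol_out_dim,
                activation=self.activation, pooling=self.mol_pooling, rng=rng_init,
            )
            head_in += self.mol_out_dim
        elif self.mol_features != "none":
            raise ConfigError(f"unknown mol_features {self.mol_features!r}")
        self.head_params_ = enc.init_head_params(head_in, rng=rng_init)

        opt_params: dict[str, np.ndarray] = {}
        opt_params.update({f"enc.{k}": v for k, v in self.encoder_params_.trainable().items()})
        opt_params.update({f"head.{k}": v for k, v in self.head_params_.trainable().items()})
        if self.mol_features == "encoder":
            opt_params.update(
                {f"mol.{k}": v for k, v in self.mol_encoder_params_.trainable().items()}
            )
        optimizer = enc.Adam(opt_params, lr=self.learning_rate)

        cfg = self.booster or BoosterConfig()
        spw = pos_weight(
            self.mode,
            sum(labeled[target][r.mol_id].n_positive for r in train_recs),
            sum(labeled[target][r.mol_id].n_negative for r in train_recs),
            self.c,
            self.weight_formula,
        )
        cfg = BoosterConfig(
            cfg.n_estimators, cfg.reg_lambda, cfg.max_depth,
            cfg.colsample_bytree, spw,
        )

        weights = enc.LossWeights(self.loss_a, self.loss_b)
        y_train = np.concatenate([labeled[target][r.mol_id].y() for r in train_recs])
        y_val = np.concatenate([labeled[target][r.mol_id].y() for r in val_recs])
        records_by_id = by_id

        history: list[dict] = []
        best = None
        for epoch in range(1, self.epochs + 1):
            order = rng_shuffle.permutation(len(instances))
            total_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                chunk = [instances[i] for i in order[start:start + self.batch_size]]
                graphs = [self._graph(r) for r, _ in chunk]
                batch = enc.batch_graphs(graphs)
                y = np.concatenate(
                    [labeled[iso][r.mol_id].y() for r, iso in chunk]
                )
                probs, F_full, caches = self._forward(
                    batch, records_by_id, training=True, rng=rng_drop
                )
                total_loss += enc.weighted_loss(probs, y, weights)
                dlogits = enc.weighted_loss_grad(probs, y, weights)
                grads: dict[str, np.ndarray] = {}
                grads["head.W"] = dlogits.T @ F_full
                grads["head.b"] = dlogits.sum(axis=0)
                dF_full = dlogits @ self.head_params_.W
                d_site = dF_full[:, : caches["F_dim"]]
                site_grads = enc.encode_sites_backward(
                    d_site, batch, self.encoder_params_, caches["site"]
                )
                grads.update({f"enc.{k}": v for k, v in site_grads.items()})
                if self.mol_features == "encoder":
                    d_mol_rows = dF_full[:, caches["F_dim"]:]
                    dmol = np.zeros((batch.n_mols, d_mol_rows.shape[1]))
                    np.add.at(dmol, batch.site_mol, d_mol_rows)
                    mol_grads = enc.molecule_embedding_backward(
                        dmol, batch, self.mol_encoder_params_, caches["mol"]
                    )
                    grads.update({f"mol.{k}": v for k, v in mol_grads.items()})
                optimizer.step(grads)

            score_now = epoch % self.booster_every == 0 or epoch == self.epochs
            if not score_now:
                continue
            X_tr, _ = self._embeddings(train_recs)
            X_va, _ = self._embeddings(val_recs)
            booster, block = fit_epoch_booster(
                X_tr, y_train, X_va, y_val, cfg, booster_seed, target
            )
            block.update(epoch=epoch, encoder_loss=total_loss)
            history.append(block)
            if best is None or block["val_jaccard"] > best["val_jaccard"]:
                best = {
                    "val_jaccard": block["val_jaccard"],
                    "epoch": epoch,
                    "booster": booster,
                    "encoder": _copy_encoder(self.encoder_params_),
                    "mol_encoder": (
                        _copy_mol_encoder(self.mol_encoder_params_)
                        if self.mol_features == "encoder" else None
                    ),
                }

        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best["epoch"]
        self.best_val_jaccard_ = best["val_jaccard"]
        self.booster_ = best["booster"]
        self.encoder_params_ = best["encoder"]
        if best["mol_encoder"] is not None:
            self.mol_encoder_params_ = best["mol_encoder"]
        self.booster_config_ = cfg
        self.threshold_ = 0.5
        self.classes_ = np.array([0, 1])
        self._graph_cache = {}
        return self

    # -- prediction -------------------------------------------------------

    def predict_sites(self, records: Sequence[MoleculeRecord]) -> PredictionReport:
        """Score every candidate site of every parsable record.

        Unparsable or failing records are reported on the error channel and
        the batch continues.  Rows are sorted by molecule then probability
        descending; SOM calls are the sites with probability > 0.5.
        """
        self._check_fitted()
        good, errors = [], []
        for rec in records:
            try:
                if rec.mol is None or rec.mol.GetNumAtoms() == 0:
                    raise DataError("empty structure")
                good.append(rec)
            except Exception as exc:
                errors.append((rec.mol_id, str(exc)))
        if not good:
            return PredictionReport(
                self.target_isoform,
                pd.DataFrame(columns=["mol_id", "site_kind", "atoms", "probability", "called"]),
                errors,
            )
        F, batch = self._embeddings(good)
        p = self.booster_.predict_proba(F)[:, 1]
        rows = []
        for k, site in enumerate(batch.sites):
            rows.append(
                {
                    "mol_id": batch.mol_ids[batch.site_mol[k]],
                    "site_kind": site.kind,
                    "atoms": "-".join(str(a) for a in site.atoms()),
                    "probability": p[k],
                    "called": bool(p[k] > self.threshold_),
                }
            )
        frame = pd.DataFrame(rows)
        order = [r.mol_id for r in good]
        frame["__m"] = pd.Categorical(frame.mol_id, categories=order, ordered=True)
        frame = (
            frame.sort_values(["__m", "probability"], ascending=[True, False])
            .drop(columns="__m")
            .reset_index(drop=True)
        )
        return PredictionReport(self.target_isoform, frame, errors)

    def predict_proba(self, X: Sequence[MoleculeRecord]) -> np.ndarray:
        """Per-site [p_negative, p_positive], sites in candidate order."""
        self._check_fitted()
        F, _ = self._embeddings(list(X))
        return self.booster_.predict_proba(F)

    def predict(self, X: Sequence[MoleculeRecord]) -> np.ndarray:
        """Per-site binary SOM calls at the fixed 0.5 threshold."""
        return (self.predict_proba(X)[:, 1] > self.threshold_).astype(int)

    def score(self, X: Sequence[MoleculeRecord], y=None) -> float:
        """Jaccard score of the SOM calls against the records' labels."""
        records = list(X)
        y_true = np.concatenate(
            [label_soms(r, self.target_isoform).y() for r in records]
        )
        from .metrics import jaccard_score_from_calls

        return jaccard_score_from_calls(y_true, self.predict(records))

    def _check_fitted(self) -> None:
        if not hasattr(self, "booster_"):
            raise RuntimeError("SitePredictor is not fitted")

    # -- persistence ------------------------------------------------------

    def save_bundle(self, path) -> None:
        """Write the trained artifact (encoder + booster + config) to a
        directory."""
        self._check_fitted()
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ep = self.encoder_params_
        np.savez(
            path / "encoder.npz",
            W_a=ep.W_a, W_m=ep.W_m, W_o=ep.W_o,
            bn_gamma=ep.bn_gamma, bn_beta=ep.bn_beta,
            bn_mean=ep.bn_mean, bn_var=ep.bn_var,
            head_W=self.head_params_.W, head_b=self.head_params_.b,
        )
        if self.mol_features == "encoder":
            mp = self.mol_encoder_params_
            np.savez(
                path / "mol_encoder.npz",
                W_a=mp.core.W_a, W_m=mp.core.W_m, W_o=mp.core.W_o,
                bn_gamma=mp.core.bn_gamma, bn_beta=mp.core.bn_beta,
                bn_mean=mp.core.bn_mean, bn_var=mp.core.bn_var,
                W_pool=mp.W_pool,
            )
        elif self.mol_features == "fixed":
            np.savez(
                path / "mol_fixed.npz",
                mean=self.mol_feat_mean_, std=self.mol_feat_std_,
            )
        # persist the raw booster; the sklearn wrapper is rebuilt on load
        self.booster_.get_booster().save_model(path / "booster.json")
        meta = dict(
            self.get_params(),
            best_epoch=self.best_epoch_,
            best_val_jaccard=self.best_val_jaccard_,
            booster_config=asdict(self.booster_config_),
        )
        meta["booster"] = asdict(self.booster) if self.booster else None
        (path / "config.json").write_text(json.dumps(meta, indent=2, default=str))
        self.history_.to_csv(path / "history.tsv", sep="\t", index=False)

    @classmethod
    def load_bundle(cls, path) -> "SitePredictor":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        best_epoch = meta.pop("best_epoch")
        best_vj = meta.pop("best_val_jaccard")
        bc = meta.pop("booster_config")
        if meta.get("booster"):
            meta["booster"] = BoosterConfig(**meta["booster"])
        est = cls(**{k: v for k, v in meta.items() if k in cls().get_params()})
        arr = np.load(path / "encoder.npz")
        est.encoder_params_ = enc.EncoderParams(
            W_a=arr["W_a"], W_m=arr["W_m"], W_o=arr["W_o"],
            bn_gamma=arr["bn_gamma"], bn_beta=arr["bn_beta"],
            bn_mean=arr["bn_mean"], bn_var=arr["bn_var"],
            depth=est.depth, dropout=est.dropout, activation=est.activation,
        )
        est.head_params_ = enc.HeadParams(W=arr["head_W"], b=arr["head_b"])
        if est.mol_features == "encoder":
            m = np.load(path / "mol_encoder.npz")
            core = enc.EncoderParams(
                W_a=m["W_a"], W_m=m["W_m"], W_o=m["W_o"],
                bn_gamma=m["bn_gamma"], bn_beta=m["bn_beta"],
                bn_mean=m["bn_mean"], bn_var=m["bn_var"],
                depth=est.mol_depth, dropout=0.0, activation=est.activation,
            )
            est.mol_encoder_params_ = enc.MoleculeEncoderParams(
                core=core, W_pool=m["W_pool"], pooling=est.mol_pooling
            )
        elif est.mol_features == "fixed":
            m = np.load(path / "mol_fixed.npz")
            est.mol_feat_mean_, est.mol_feat_std_ = m["mean"], m["std"]
        booster = xgb.XGBClassifier()
        raw = xgb.Booster()
        raw.load_model(path / "booster.json")
        booster._Booster = raw
        booster.n_classes_ = 2
        est.booster_ = booster
        est.booster_config_ = BoosterConfig(**bc)
        est.best_epoch_ = best_epoch
        est.best_val_jaccard_ = best_vj
        est.threshold_ = 0.5
        est.classes_ = np.array([0, 1])
        est.history_ = pd.read_csv(path / "history.tsv", sep="\t")
        est._graph_cache = {}
        return est


def _copy_encoder(p: enc.EncoderParams) -> enc.EncoderParams:
    return enc.EncoderParams(
        W_a=p.W_a.copy(), W_m=p.W_m.copy(), W_o=p.W_o.copy(),
        bn_gamma=p.bn_gamma.copy(), bn_beta=p.bn_beta.copy(),
        bn_mean=p.bn_mean.copy(), bn_var=p.bn_var.copy(),
        depth=p.depth, dropout=p.dropout,
        activation=p.activation, leaky_slope=p.leaky_slope,
    )


def _copy_mol_encoder(p: enc.MoleculeEncoderParams) -> enc.MoleculeEncoderParams:
    return enc.MoleculeEncoderParams(
        core=_copy_encoder(p.core), W_pool=p.W_pool.copy(), pooling=p.pooling
    )


def train(
    records: Sequence[MoleculeRecord],
    target_isoform: str,
    mode: str = "precision",
    config: Mapping | None = None,
    seed: int = 0,
) -> SitePredictor:
    """Thin functional wrapper: fit a :class:`SitePredictor`."""
    est = SitePredictor(
        target_isoform=target_isoform, mode=mode, random_state=seed,
        **dict(config or {}),
    )
    return est.fit(records)
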