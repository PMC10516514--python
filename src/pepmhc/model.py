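"""The binding-affinity network.

A pan-specific regression model mapping (peptide, MHC pseudo sequence)
to affinity in (0, 1):

1. both sequences pass through a shared learned residue embedding
   (``d`` = 16 by default);
2. a *position-wise gated layer* applies an independent gated linear
   unit at every peptide position, letting the model attenuate or pass
   residue information per position — the mechanism for anchor-position
   awareness across peptide lengths;
3. two *binding-interaction convolution layers* (BICLs) scan the peptide
   with kernels that are not free parameters but are **generated from
   the MHC embedding matrix** (``K_i = f(U_i Y)``), so the filter bank
   is conditioned on the allele; one BICL reads the raw embedding, the
   other the gated embedding, and their batch-normalized outputs are
   summed residually;
4. a stack of position-wise fully connected layers, max-pooling over
   positions, and a sigmoid output head produce the affinity.

Kernel sizes 9/11/13 (counts 128/64/32) cover the common peptide
lengths; larger kernels are convolved over a zero-padded peptide so all
size classes emit the same output width L - 9 + 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import (
    VOCABULARY,
    MHCAllele,
    PeptideRecord,
    encode_peptide,
    encode_pseudo,
)


@dataclass
class ModelConfig:
    model_length: int = 15
    embed_dim: int = 16
    kernel_spec: dict[int, int] = field(default_factory=lambda: {9: 128, 11: 64, 13: 32})
    fc_dims: list[int] = field(default_factory=lambda: [256, 128])
    dropout_rate: float = 0.25
    use_gate: bool = True
    use_residual: bool = True
    tie_gate: bool = False
    embedding_mode: str = "learned"  # or "one_hot"

    def __post_init__(self) -> None:
        for k in self.kernel_spec:
            if k % 2 == 0 or k < 9:
                raise ValueError(f"kernel size {k} must be odd and >= 9")
        if self.model_length < 9:
            raise ValueError("model_length must be >= 9")
        if not self.fc_dims:
            raise ValueError("fc_dims must be nonempty")
        if self.embedding_mode not in ("learned", "one_hot"):
            raise ValueError(f"unknown embedding_mode {self.embedding_mode!r}")
        if self.embedding_mode == "one_hot":
            self.embed_dim = VOCABULARY.size

    @property
    def conv_width(self) -> int:
        """Output width of every BICL size class (L - 9 + 1)."""
        return self.model_length - 9 + 1

    @property
    def total_kernels(self) -> int:
        return sum(self.kernel_spec.values())

    def to_json(self) -> str:
        d = asdict(self)
        # ordered pairs: size-class order defines the channel layout
        d["kernel_spec"] = [[k, v] for k, v in d["kernel_spec"].items()]
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["kernel_spec"] = {int(k): v for k, v in d["kernel_spec"]}
        return cls(**d)


class Model:
    """Parameter container plus forward passes (training and eval mode)."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.params: dict[str, Tensor] = {}
        self.bn_state: dict[str, np.ndarray] = {}
        self._init(np.random.default_rng(seed))

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------
    def _init(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d, L = cfg.embed_dim, cfg.model_length
        V = VOCABULARY.size

        if cfg.embedding_mode == "one_hot":
            emb = np.eye(V)
            self.params["embedding"] = Tensor(emb, requires_grad=False)
        else:
            # the pad row is initialized like any residue: a salient pad
            # vector lets the convolutions read the peptide's C-terminal
            # boundary, which length-shifting anchors depend on
            emb = rng.normal(0.0, 1.0, (V, d)) / np.sqrt(d)
            self.params["embedding"] = Tensor(emb, requires_grad=True)

        gshape = (d, d) if cfg.tie_gate else (L, d, d)
        bshape = (d,) if cfg.tie_gate else (L, d)
        for name in ("gate.W", "gate.V"):
            self.params[name] = Tensor(rng.normal(0, 1 / np.sqrt(d), gshape), requires_grad=True)
        for name in ("gate.b", "gate.c"):
            self.params[name] = Tensor(np.zeros(bshape), requires_grad=True)

        for branch in (1, 2):
            for k, H in cfg.kernel_spec.items():
                self.params[f"bicl{branch}.U{k}"] = Tensor(
                    rng.normal(0, np.sqrt(2.0 / 34.0), (H, k, 34)), requires_grad=True
                )
                self.params[f"bicl{branch}.b{k}"] = Tensor(np.zeros(H), requires_grad=True)
            C = cfg.total_kernels
            self.params[f"bn_bicl{branch}.gamma"] = Tensor(np.ones(C), requires_grad=True)
            self.params[f"bn_bicl{branch}.beta"] = Tensor(np.zeros(C), requires_grad=True)
            self.bn_state[f"bn_bicl{branch}.mean"] = np.zeros(C, dtype=ad.DTYPE)
            self.bn_state[f"bn_bicl{branch}.var"] = np.ones(C, dtype=ad.DTYPE)

        prev = cfg.total_kernels
        for n, width in enumerate(cfg.fc_dims, 1):
            # no linear bias: the following batch norm is shift-invariant,
            # so its beta is the effective bias
            self.params[f"fc{n}.W"] = Tensor(
                rng.normal(0, np.sqrt(2.0 / prev), (prev, width)), requires_grad=True
            )
            self.params[f"bn_fc{n}.gamma"] = Tensor(np.ones(width), requires_grad=True)
            self.params[f"bn_fc{n}.beta"] = Tensor(np.zeros(width), requires_grad=True)
            self.bn_state[f"bn_fc{n}.mean"] = np.zeros(width, dtype=ad.DTYPE)
            self.bn_state[f"bn_fc{n}.var"] = np.ones(width, dtype=ad.DTYPE)
            prev = width

        self.params["out.w"] = Tensor(
            rng.normal(0, 1 / np.sqrt(prev), (prev, 1)), requires_grad=True
        )
        self.params["out.b"] = Tensor(np.zeros(1), requires_grad=True)

    def trainable(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.trainable().values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # ------------------------------------------------------------------
    # forward pieces (Tensor level, batched)
    # ------------------------------------------------------------------
    def _embed_rows(self, idx: np.ndarray) -> Tensor:
        """(N, S) integer indices -> (N, S, d) embedding rows."""
        N, S = idx.shape
        flat = ad.take(self.params["embedding"], idx.reshape(-1))
        return ad.reshape(flat, (N, S, self.config.embed_dim))

    def _gate_t(self, X: Tensor) -> Tensor:
        W, Vt = self.params["gate.W"], self.params["gate.V"]
        b, c = self.params["gate.b"], self.params["gate.c"]
        spec = "oi,bli->blo" if self.config.tie_gate else "loi,bli->blo"
        gate = ad.sigmoid(ad.add(ad.einsum2(spec, W, X), b))
        value = ad.add(ad.einsum2(spec, Vt, X), c)
        return ad.mul(gate, value)

    def _kernels_t(self, Yu: Tensor, branch: int) -> dict[int, Tensor]:
        """Generate per-allele kernels K = relu(U Y) for each size class.

        Yu holds the embeddings of the *unique* pseudo sequences in the
        batch; kernels are flattened to (n_unique, H, k*d).
        """
        out = {}
        d = self.config.embed_dim
        for k, H in self.config.kernel_spec.items():
            U = self.params[f"bicl{branch}.U{k}"]
            K = ad.relu(ad.einsum2("hkq,nqd->nhkd", U, Yu))
            out[k] = ad.reshape(K, (Yu.shape[0], H, k * d))
        return out

    def _bicl_t(self, Xin: Tensor, Ku: dict[int, Tensor], inv: np.ndarray, branch: int) -> Tensor:
        """One BICL: allele-conditioned convolution -> (B, total_kernels, J).

        Examples sharing an allele are grouped so each size class runs
        one GEMM per allele in the batch rather than one per example.
        """
        cfg = self.config
        B, L, d = Xin.shape
        J = cfg.conv_width
        n_uniq = Ku[next(iter(Ku))].shape[0]
        groups = [np.flatnonzero(inv == u) for u in range(n_uniq)]
        restore = np.argsort(np.concatenate(groups), kind="stable")
        outs = []
        for k, H in cfg.kernel_spec.items():
            pad = (k - 9) // 2
            Xp = Xin
            if pad:
                z = Tensor(np.zeros((B, pad, d)))
                Xp = ad.concat([z, Xin, z], axis=1)
            win = ad.reshape(ad.windows(Xp, k), (B, J, k * d))
            pieces = []
            for u, idx in enumerate(groups):
                if len(idx) == 0:
                    continue
                wg = ad.reshape(ad.take(win, idx), (len(idx) * J, k * d))
                Kg = ad.transpose(ad.reshape(ad.take(Ku[k], np.array([u])), (H, k * d)), (1, 0))
                pieces.append(ad.reshape(ad.matmul(wg, Kg), (len(idx), J, H)))
            conv = ad.take(ad.concat(pieces, axis=0), restore)  # (B, J, H)
            bias = ad.reshape(self.params[f"bicl{branch}.b{k}"], (1, 1, H))
            outs.append(ad.transpose(ad.relu(ad.add(conv, bias)), (0, 2, 1)))
        return ad.concat(outs, axis=1)

    def _bn_t(self, flat: Tensor, name: str, training: bool) -> Tensor:
        return ad.batch_norm(
            flat,
            self.params[f"{name}.gamma"],
            self.params[f"{name}.beta"],
            self.bn_state[f"{name}.mean"],
            self.bn_state[f"{name}.var"],
            training,
        )

    @staticmethod
    def _to_flat(C: Tensor) -> Tensor:
        """(B, C, J) -> (B*J, C) position-major flattening for BN/FC."""
        B, ch, J = C.shape
        return ad.reshape(ad.transpose(C, (0, 2, 1)), (B * J, ch))

    def forward_batch(
        self,
        pep_idx: np.ndarray,
        pseudo_idx: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Predict affinities for a batch; returns a (B,) Tensor.

        ``pep_idx`` is (B, L) and ``pseudo_idx`` (B, 34), both integer
        encoded.  Training mode uses batch statistics and dropout and
        requires ``rng``.
        """
        cfg = self.config
        B = pep_idx.shape[0]
        J = cfg.conv_width
        if training and rng is None:
            raise ValueError("training-mode forward requires an rng for dropout")

        uniq, inv = np.unique(pseudo_idx, axis=0, return_inverse=True)
        inv = np.asarray(inv).ravel()
        Yu = self._embed_rows(uniq)
        X = self._embed_rows(pep_idx)
        Xg = self._gate_t(X) if cfg.use_gate else X

        K2 = self._kernels_t(Yu, 2)
        C2 = self._bicl_t(Xg, K2, inv, 2)
        n2 = self._bn_t(self._to_flat(C2), "bn_bicl2", training)
        if cfg.use_residual:
            K1 = self._kernels_t(Yu, 1)
            C1 = self._bicl_t(X, K1, inv, 1)
            n1 = self._bn_t(self._to_flat(C1), "bn_bicl1", training)
            C0 = ad.relu(ad.add(n1, n2))
        else:
            C0 = ad.relu(n2)

        Z = C0  # (B*J, channels)
        for n in range(1, len(cfg.fc_dims) + 1):
            Z = ad.matmul(Z, self.params[f"fc{n}.W"])
            Z = ad.relu(self._bn_t(Z, f"bn_fc{n}", training))
            if training and cfg.dropout_rate > 0:
                Z = ad.dropout(Z, cfg.dropout_rate, rng)

        g = ad.amax(ad.reshape(Z, (B, J, cfg.fc_dims[-1])), axis=1)  # (B, d_N)
        y = ad.sigmoid(ad.add(ad.matmul(g, self.params["out.w"]), self.params["out.b"]))
        return ad.reshape(y, (B,))

    # ------------------------------------------------------------------
    # single-instance operation surface (eval mode, NumPy in/out)
    # ------------------------------------------------------------------
    def embed(self, indices: np.ndarray) -> np.ndarray:
        """Look up embedding rows for an index vector."""
        idx = np.asarray(indices, dtype=np.int64)
        if idx.min() < 0 or idx.max() >= VOCABULARY.size:
            raise IndexError("index outside vocabulary")
        return self.params["embedding"].data[idx]

    def position_gate(self, X: np.ndarray) -> np.ndarray:
        """Apply the per-position gated linear units to an (L, d) matrix."""
        return self._gate_t(Tensor(X[None])).data[0]

    def generate_kernels(self, Y: np.ndarray, branch: int = 2) -> dict[int, np.ndarray]:
        """Kernels K_i = relu(U_i Y) from one MHC embedding matrix (34, d)."""
        Ku = self._kernels_t(Tensor(Y[None]), branch)
        d = self.config.embed_dim
        return {
            k: Ku[k].data[0].reshape(self.config.kernel_spec[k], k, d)
            for k in self.config.kernel_spec
        }

    def bicl_forward(self, X_in: np.ndarray, Y: np.ndarray, branch: int = 2) -> np.ndarray:
        """One BICL on a single (L, d), (34, d) pair -> (total_kernels, J)."""
        Ku = self._kernels_t(Tensor(Y[None]), branch)
        C = self._bicl_t(Tensor(X_in[None]), Ku, np.zeros(1, dtype=np.int64), branch)
        return C.data[0]

    def resbicl_forward(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Residual combination of both BICLs (eval-mode normalization)."""
        Xt, Yt = Tensor(X[None]), Tensor(Y[None])
        inv = np.zeros(1, dtype=np.int64)
        Xg = self._gate_t(Xt) if self.config.use_gate else Xt
        n2 = self._bn_t(self._to_flat(self._bicl_t(Xg, self._kernels_t(Yt, 2), inv, 2)), "bn_bicl2", False)
        if self.config.use_residual:
            n1 = self._bn_t(self._to_flat(self._bicl_t(Xt, self._kernels_t(Yt, 1), inv, 1)), "bn_bicl1", False)
            out = ad.relu(ad.add(n1, n2))
        else:
            out = ad.relu(n2)
        J = self.config.conv_width
        return out.data.reshape(J, -1).T  # back to (channels, J)

    def head_forward(self, C0: np.ndarray) -> float:
        """FC stack + max-pool + sigmoid head on one (channels, J) matrix."""
        cfg = self.config
        J = cfg.conv_width
        Z = Tensor(np.ascontiguousarray(C0.T))  # (J, channels)
        for n in range(1, len(cfg.fc_dims) + 1):
            Z = ad.matmul(Z, self.params[f"fc{n}.W"])
            Z = ad.relu(self._bn_t(Z, f"bn_fc{n}", False))
        g = ad.amax(ad.reshape(Z, (1, J, cfg.fc_dims[-1])), axis=1)
        y = ad.sigmoid(ad.add(ad.matmul(g, self.params["out.w"]), self.params["out.b"]))
        return float(y.data[0, 0])

    def forward(self, peptide: PeptideRecord | str, allele: MHCAllele) -> float:
        """Eval-mode prediction for one (peptide, allele) pair."""
        return float(self.predict_encoded(
            encode_peptide(peptide, self.config.model_length)[None],
            encode_pseudo(allele)[None],
        )[0])

    def predict_encoded(
        self, pep_idx: np.ndarray, pseudo_idx: np.ndarray, batch_size: int = 512
    ) -> np.ndarray:
        """Deterministic eval-mode predictions for encoded arrays."""
        outs = []
        for lo in range(0, pep_idx.shape[0], batch_size):
            hi = lo + batch_size
            outs.append(self.forward_batch(pep_idx[lo:hi], pseudo_idx[lo:hi]).data)
        return np.concatenate(outs) if outs else np.zeros(0)

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"param:{k}": v.data for k, v in self.params.items()}
        arrays.update({f"bn:{k}": v for k, v in self.bn_state.items()})
        np.savez(
            path,
            __config__=np.frombuffer(self.config.to_json().encode(), dtype=np.uint8),
            __vocab__=np.frombuffer(VOCABULARY.checksum().encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as blob:
            cfg = ModelConfig.from_json(bytes(blob["__config__"]).decode())
            vocab = bytes(blob["__vocab__"]).decode()
            if vocab != VOCABULARY.checksum():
                raise ValueError("checkpoint was written with a different vocabulary")
            model = cls(cfg, seed=0)
            for k in model.params:
                data = blob[f"param:{k}"]
                if data.shape != model.params[k].data.shape:
                    raise ValueError(f"shape mismatch for {k}")
                model.params[k].data = data.astype(ad.DTYPE)
            for k in model.bn_state:
                model.bn_state[k] = blob[f"bn:{k}"].astype(ad.DTYPE)
        return model
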