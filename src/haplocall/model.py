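"""Generative haplotype model: transformer encoder + two parallel decoders.

The model reads an encoded pileup window (positions x reads x 10 features)
and autoregressively generates two haplotype sequences as 4-mer tokens, one
per decoder.  The two decoders do not share parameters; the encoder is the
only channel through which the model can decide which haplotype each decoder
must produce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from . import nn

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
KMER_SIZE = 4
VOCAB_SIZE = 4 ** KMER_SIZE  # 256
MAX_OUTPUT_TOKENS = 37       # 148 bases


class TokenizationError(ValueError):
    pass


def tokenize(sequence: str) -> np.ndarray:
    """Map a DNA sequence of length 4m to m big-endian 4-mer token ids.

    Base order A=0, C=1, G=2, T=3; e.g. ``ACGT`` -> 0*64 + 1*16 + 2*4 + 3.
    """
    if len(sequence) % KMER_SIZE != 0:
        raise TokenizationError(
            f"sequence length {len(sequence)} is not a multiple of {KMER_SIZE}")
    seq = sequence.upper()
    try:
        codes = np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise TokenizationError(f"unsupported base {exc} in sequence") from exc
    codes = codes.reshape(-1, KMER_SIZE)
    weights = np.array([64, 16, 4, 1], dtype=np.int64)
    return codes @ weights


def detokenize(ids) -> str:
    ids = np.asarray(ids, dtype=np.int64)
    if ids.size and (ids.min() < 0 or ids.max() >= VOCAB_SIZE):
        raise TokenizationError("token id outside [0, 255]")
    out = []
    for t in ids:
        out.append(BASES[(t >> 6) & 3] + BASES[(t >> 4) & 3]
                   + BASES[(t >> 2) & 3] + BASES[t & 3])
    return "".join(out)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``embedding_dim`` is the encoder model dimension; both decoders run at
    ``decoder_dim`` (256 by default, the 4-mer vocabulary size).  ``base_embed_dim``
    (d) is the per-cell embedding width before flattening along the read axis,
    so each genomic position becomes one encoder token of size d*r.
    """

    encoder_layers: int = 6
    encoder_heads: int = 8
    embedding_dim: int = 800
    decoder_layers: int = 4
    decoder_heads: int = 4
    base_embed_dim: int = 12
    max_reads: int = 150
    window_size: int = 150
    decoder_dim: int = 256
    ff_mult: int = 1
    dropout: float = 0.1
    kmer_size: int = KMER_SIZE
    vocab_size: int = VOCAB_SIZE
    max_output_tokens: int = MAX_OUTPUT_TOKENS

    def __post_init__(self):
        if self.vocab_size != 4 ** self.kmer_size:
            raise ValueError("vocab_size must equal 4**kmer_size")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


#: Named presets.  The three large presets follow the published parameter
#: grid (encoder layers / heads / embedding dim / decoder layers / heads);
#: ``tiny`` is a CPU-scale configuration for testing and desk-scale runs.
PRESETS: dict[str, ModelConfig] = {
    "30M": ModelConfig(6, 8, 800, 4, 4),
    "50M": ModelConfig(8, 8, 960, 8, 4),
    "100M": ModelConfig(10, 8, 1280, 10, 10),
    "tiny": ModelConfig(encoder_layers=2, encoder_heads=4, embedding_dim=64,
                        decoder_layers=2, decoder_heads=4, base_embed_dim=8,
                        max_reads=32, decoder_dim=64, dropout=0.0),
}


def sinusoidal_encoding(length: int, dim: int,
                        positions: np.ndarray | None = None) -> np.ndarray:
    """Standard 1-D sinusoidal positional encoding [length, dim].

    ``positions`` overrides the default integer index 0..length-1 (used to
    express one axis in units of another, e.g. genomic columns in 4-mer
    token units).
    """
    if positions is None:
        positions = np.arange(length, dtype=np.float32)
    pos = np.asarray(positions, dtype=np.float32)[:, None]
    i = np.arange(dim, dtype=np.float32)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.zeros((length, dim), dtype=np.float32)
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


def sinusoidal_encoding_2d(n_pos: int, n_reads: int, dim: int) -> np.ndarray:
    """2-D sinusoidal encoding [n_pos, n_reads, dim].

    Half the channels vary with genomic position, half with read row, so
    the model can distinguish both axes after the read dimension is
    flattened.
    """
    if dim % 2:
        raise ValueError("2-D positional encoding needs an even channel count")
    half = dim // 2
    pos_enc = sinusoidal_encoding(n_pos, half)
    read_enc = sinusoidal_encoding(n_reads, half)
    out = np.zeros((n_pos, n_reads, dim), dtype=np.float32)
    out[:, :, :half] = pos_enc[:, None, :]
    out[:, :, half:] = read_enc[None, :, :]
    return out


def _largest_divisor_head_count(dim: int, requested: int) -> int:
    h = min(requested, dim)
    while dim % h:
        h -= 1
    return h


class HaplotypeTransformer(nn.Module):
    """Encoder/double-decoder model over encoded pileup windows."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        cfg = config
        dec_heads = _largest_divisor_head_count(cfg.decoder_dim, cfg.decoder_heads)
        if dec_heads != cfg.decoder_heads:
            cfg = replace(cfg, decoder_heads=dec_heads)
        self.config = cfg
        g, r, d = cfg.window_size, cfg.max_reads, cfg.base_embed_dim

        self.cell_embed = nn.Linear(10, d, rng)
        self._pe2d = sinusoidal_encoding_2d(g, r, d)[None]  # [1, g, r, d]
        self.input_proj = nn.Linear(d * r, cfg.embedding_dim, rng)
        self.encoder_layers = [
            nn.TransformerEncoderLayer(cfg.embedding_dim, cfg.encoder_heads,
                                       cfg.ff_mult * cfg.embedding_dim,
                                       cfg.dropout, rng)
            for _ in range(cfg.encoder_layers)
        ]
        self.memory_proj = nn.Linear(cfg.embedding_dim, cfg.decoder_dim, rng)
        self._pe1d_mem = sinusoidal_encoding(g, cfg.decoder_dim)[None]
        # decoder positions are expressed in genomic-column units (token t
        # starts at column 4t) so cross-attention queries and memory keys
        # share one positional scale and each head can specialize on a fixed
        # small offset within the 4-mer
        self._pe1d_dec = sinusoidal_encoding(
            cfg.max_output_tokens, cfg.decoder_dim,
            positions=np.arange(cfg.max_output_tokens,
                                dtype=np.float32) * cfg.kmer_size)[None]

        def make_decoder():
            layers = [
                nn.TransformerDecoderLayer(cfg.decoder_dim, cfg.decoder_heads,
                                           cfg.ff_mult * cfg.decoder_dim,
                                           cfg.dropout, rng)
                for _ in range(cfg.decoder_layers)
            ]
            # cross-attention query/key projections start at the identity so
            # the initial attention pattern follows the positional-encoding
            # diagonal (decoder position 4t onto memory column ~4t); without
            # this, attention over 150 columns starts uniform and the copy
            # signal is too dilute to bootstrap at small training scales
            eye = np.eye(cfg.decoder_dim, dtype=np.float32)
            for layer in layers:
                layer.cross_attn.q_proj.weight.data = eye.copy()
                layer.cross_attn.k_proj.weight.data = eye.copy()
            return {
                "token_embed": nn.Embedding(cfg.vocab_size, cfg.decoder_dim, rng),
                "start": nn.Parameter(rng.normal(0.0, 0.02,
                                                 size=(1, 1, cfg.decoder_dim))),
                "layers": layers,
                "out_proj": nn.Linear(cfg.decoder_dim, cfg.vocab_size, rng),
            }

        # two parallel decoders without parameter sharing
        for hap in (0, 1):
            parts = make_decoder()
            setattr(self, f"dec{hap}_token_embed", parts["token_embed"])
            setattr(self, f"dec{hap}_start", parts["start"])
            setattr(self, f"dec{hap}_layers", parts["layers"])
            setattr(self, f"dec{hap}_out_proj", parts["out_proj"])

        self._train_rng = np.random.default_rng(seed + 1)
        self.training = False

    # ------------------------------------------------------------------
    def train_mode(self, on: bool = True) -> None:
        self.training = on

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # ------------------------------------------------------------------
    def encoder_forward(self, regions: np.ndarray) -> nn.Tensor:
        """Encode a batch of regions [B, g, r, 10] into decoder memory.

        Returns the cross-attention memory [B, g, decoder_dim] with the 1-D
        positional encoding already added.
        """
        x = np.asarray(regions, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        g, r = self.config.window_size, self.config.max_reads
        if x.shape[1:] != (g, r, 10):
            raise ValueError(f"expected region shape [B, {g}, {r}, 10], "
                             f"got {x.shape}")
        b = x.shape[0]
        h = self.cell_embed(nn.Tensor(x))                  # [B, g, r, d]
        h = h + nn.Tensor(self._pe2d)
        h = h.reshape(b, g, r * self.config.base_embed_dim)
        h = self.input_proj(h)                             # [B, g, E]
        for layer in self.encoder_layers:
            h = layer(h, self._train_rng, self.training)
        mem = self.memory_proj(h)                          # [B, g, Dd]
        mem = mem + nn.Tensor(self._pe1d_mem)
        return mem

    def _decoder_parts(self, decoder_id: int):
        if decoder_id not in (0, 1):
            raise ValueError("decoder_id must be 0 or 1")
        p = f"dec{decoder_id}_"
        return (getattr(self, p + "token_embed"), getattr(self, p + "start"),
                getattr(self, p + "layers"), getattr(self, p + "out_proj"))

    def decoder_forward(self, memory: nn.Tensor, decoder_id: int,
                        tokens: np.ndarray) -> nn.Tensor:
        """Teacher-forced decoder pass.

        ``tokens`` [B, T] are the ground-truth tokens; the decoder input at
        step 0 is a learned start embedding and at step t>0 token t-1, so the
        returned logits [B, T, 256] predict tokens 0..T-1.
        """
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim == 1:
            tokens = tokens[None]
        b, t = tokens.shape
        if t > self.config.max_output_tokens:
            raise ValueError(f"decoder length {t} exceeds the "
                             f"{self.config.max_output_tokens}-token cap")
        embed, start, layers, out_proj = self._decoder_parts(decoder_id)
        # broadcast the learned start embedding over the batch (grad flows
        # back through the add's unbroadcast reduction)
        start_b = start + nn.Tensor(np.zeros((b, 1, self.config.decoder_dim),
                                             dtype=np.float32))
        if t > 1:
            tok = embed(tokens[:, :t - 1])
            x = nn.concat([start_b, tok], axis=1)
        else:
            x = start_b
        x = x + nn.Tensor(self._pe1d_dec[:, :t])
        mask = nn.causal_mask(t)
        for layer in layers:
            x = layer(x, memory, mask, self._train_rng, self.training)
        return out_proj(x)

    def decode_step(self, memory: nn.Tensor, decoder_id: int,
                    previous_tokens) -> np.ndarray:
        """Next-token probability distribution given the emitted prefix."""
        prev = np.asarray(previous_tokens, dtype=np.int64).reshape(-1)
        if prev.size > self.config.max_output_tokens:
            raise ValueError("prefix longer than the decoding cap")
        t = prev.size + 1
        if t > self.config.max_output_tokens:
            raise ValueError("decoding past the token cap")
        tokens = np.zeros((1, t), dtype=np.int64)
        if prev.size:
            # teacher tokens: logits at step i predict token i, so the target
            # row content past the prefix is irrelevant to the last step
            tokens[0, :prev.size] = prev
            tokens[0, prev.size] = 0
        logits = self.decoder_forward(memory, decoder_id, tokens)
        last = logits.data[0, -1]
        e = np.exp(last - last.max())
        return e / e.sum()

    def greedy_decode(self, region: np.ndarray,
                      n_tokens: int | None = None) -> "HaplotypePrediction":
        """Greedily generate both haplotypes for one encoded region.

        At each step the single highest-probability 4-mer is appended
        (ties resolve to the lowest token id) until ``n_tokens`` (default:
        the 37-token / 148-base cap) have been generated.
        """
        was_training = self.training
        self.training = False
        try:
            cap = self.config.max_output_tokens if n_tokens is None else n_tokens
            cap = min(cap, self.config.max_output_tokens)
            memory = self.encoder_forward(region)
            haps, probs = [], []
            for decoder_id in (0, 1):
                ids: list[int] = []
                token_probs: list[float] = []
                for _ in range(cap):
                    dist = self.decode_step(memory, decoder_id, ids)
                    tok = int(np.argmax(dist))
                    ids.append(tok)
                    token_probs.append(float(dist[tok]))
                haps.append(detokenize(ids))
                probs.append(np.asarray(token_probs))
        finally:
            self.training = was_training
        return HaplotypePrediction(hap0=haps[0], hap1=haps[1],
                                   token_probs0=probs[0], token_probs1=probs[1])

    def greedy_decode_batch(self, regions: np.ndarray,
                            n_tokens: int | None = None
                            ) -> list["HaplotypePrediction"]:
        """Batched greedy decoding (one forward per step for all regions)."""
        was_training = self.training
        self.training = False
        try:
            regions = np.asarray(regions, dtype=np.float32)
            if regions.ndim == 3:
                regions = regions[None]
            b = regions.shape[0]
            cap = self.config.max_output_tokens if n_tokens is None else n_tokens
            cap = min(cap, self.config.max_output_tokens)
            memory = self.encoder_forward(regions)
            out_ids = np.zeros((2, b, cap), dtype=np.int64)
            out_probs = np.zeros((2, b, cap), dtype=np.float32)
            for decoder_id in (0, 1):
                for t in range(cap):
                    tokens = np.zeros((b, t + 1), dtype=np.int64)
                    if t:
                        tokens[:, :t] = out_ids[decoder_id, :, :t]
                    logits = self.decoder_forward(memory, decoder_id, tokens)
                    last = logits.data[:, -1]
                    last = last - last.max(axis=-1, keepdims=True)
                    p = np.exp(last)
                    p /= p.sum(axis=-1, keepdims=True)
                    pick = np.argmax(p, axis=-1)
                    out_ids[decoder_id, :, t] = pick
                    out_probs[decoder_id, :, t] = p[np.arange(b), pick]
        finally:
            self.training = was_training
        return [
            HaplotypePrediction(
                hap0=detokenize(out_ids[0, i]), hap1=detokenize(out_ids[1, i]),
                token_probs0=out_probs[0, i].copy(),
                token_probs1=out_probs[1, i].copy())
            for i in range(b)
        ]

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8)
        np.savez(path if str(path).endswith(".npz") else str(path) + ".npz",
                 **state)

    @classmethod
    def load(cls, path: str) -> "HaplotypeTransformer":
        with np.load(path) as data:
            cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
            model = cls(cfg, seed=0)
            model.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"})
        return model


@dataclass
class HaplotypePrediction:
    """Two generated haplotype sequences with per-token probabilities."""

    hap0: str
    hap1: str
    token_probs0: np.ndarray
    token_probs1: np.ndarray
    window: object = None

    def haplotypes(self) -> tuple[str, str]:
        return self.hap0, self.hap1
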