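"""Train the recurrent autoencoder baselines (AE and VAE) on short windows.

The encoder compresses a window into a latent code; the decoder, fed the
code and its previous output at every step, reconstructs the window.  The
variational variant predicts a mean and standard deviation and draws the
code via the reparameterization d = mu + sigma * eps, adding a KL penalty
to the standard-normal prior.
"""

import numpy as np

from ecggan import AEConfig, SynthConfig, ae_loss, generate_dataset, train_autoencoder

windows = generate_dataset(
    SynthConfig(duration=2.0, sampling_rate=50.0, seed=1), n_records=4,
    window_length=50,
)
print(f"training pool: {len(windows)} windows of 50 samples")

for variational in (False, True):
    cfg = AEConfig(cell="lstm", hidden_units=12, latent_dim=6, seq_len=50,
                   variational=variational, seed=0)
    model, history = train_autoencoder(
        cfg, windows, epochs=30, batch_size=4, lr=1e-2, seed=0
    )
    name = "LSTM-VAE" if variational else "LSTM-AE"
    print(f"{name}: loss {history.d_losses[0]:.4f} -> {history.d_losses[-1]:.4f} "
          f"over {history.n_epochs} epochs")
    batch = np.stack([w.values for w in windows[:4]])
    recon = model(batch, teacher_forcing=True)[0].data
    print(f"  teacher-forced reconstruction MSE on 4 windows: "
          f"{ae_loss(batch, recon):.4f}")
print("(the VAE loss includes its KL term, so the two are not directly comparable)")
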