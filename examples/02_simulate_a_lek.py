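"""Forward-simulate a synthetic lek and summarise per-male outcomes.

Generates the field-scale preset (about two dozen males over a few sessions),
validates the resulting event stream against the support constraints, and
prints per-male fight and mating metrics.  Win rate is wins/(wins+losses);
"available" is time present with females on the lek and not locked in a
fight or copulation — the time a male could actually be solicited.
"""

from lekrem import validate_history
from lekrem.synth import generate_dataset, field_scale_config

cfg = field_scale_config(seed=42, n_days=4)
ds = generate_dataset(cfg)
report = validate_history(ds.events, ds.roster, ds.day_gaps)
print(f"{len(ds.events)} events over {len(cfg.days)} days "
      f"(valid: {report.ok})")
print("events by kind:", dict(sorted(report.counts.items())))

from lekrem import summarize

metrics = summarize(ds.events, ds.roster)
print(f"\n{'male':>5} {'fights':>7} {'win rate':>9} {'solic.':>7} "
      f"{'copul.':>7} {'avail (h)':>10}")
for aid, m in metrics.items():
    if m.total_fights == 0 and m.solicitations == 0:
        continue
    wr = "-" if m.win_rate is None else f"{m.win_rate:.2f}"
    print(f"{aid:>5} {m.total_fights:>7} {wr:>9} {m.solicitations:>7} "
          f"{m.copulations:>7} {m.time_available_to_mate / 3600:>10.2f}")
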