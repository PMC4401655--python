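# Putatively ectomycorrhizal basidiomycete families.
# One taxon per line; lines starting with '#' are ignored.
# Edit or replace via the `whitelist` argument of read_taxonomy().
Amanitaceae
Boletaceae
Cantharellaceae
Clavulinaceae
Cortinariaceae
Hydnangiaceae
Inocybaceae
Russulaceae
Sclerodermataceae
Sebacinaceae
Thelephoraceae
Tricholomataceae
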