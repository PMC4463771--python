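# Fragment rule table: which structure-specific fragments are predicted per
# lipid class and polarity. Editable config; adding a class means adding rows.
# kinds: neutral-loss-of-fa | fa-anion | headgroup | serine-loss
# lipid_class	polarity	kind
TAG	+	neutral-loss-of-fa
PC	+	headgroup
SM	+	headgroup
PC	-	fa-anion
PE	-	fa-anion
PI	-	fa-anion
PS	-	fa-anion
PS	-	serine-loss
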