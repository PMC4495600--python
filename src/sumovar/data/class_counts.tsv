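type	disease	polymorphism	unclassified
I+	69	138	28
I-	38	119	19
II+	157	419	47
II-	162	452	68
III	752	2501	293
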