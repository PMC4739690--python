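('Hyrachyus eximius',('Trigonias osborni',('Diceratherium niobrarense',('Menoceras arikarense',('Diceros bicornis',('Aphelops mutilis','Teleoceras hicksi'))))));
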