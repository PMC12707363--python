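{
  "_comment": "Synthetic stand-in for a boundary-annotated reference intein (generated by splicescout.synthetic.make_reference_intein, seed 2024). It exists so N1/N2 boundary transfer can be demonstrated and tested; real reference inteins with a published N1/N2 border are not shipped. Replace with your own reference JSON ({id, residues, boundary}) for real analyses.",
  "id": "synthetic-reference_intN",
  "residues": "SNAGTTLNLFAGLAGGLTGGSQVQFASQNAGSAFQNSQTTAGNSVTNLVGTTNVSTATGARQDERDQEPERQANSSNENNQREDPEEGDKRERREPAGSEAASKGDSGSRGERKPQDEPG",
  "boundary": 60
}
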